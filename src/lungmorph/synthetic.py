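"""Synthetic cohorts: images, masks and clinical/genetic tables with plantable signal.

The generator emulates the statistical structure of a two-subtype NSCLC cohort
(LUAD coded 1, LUSC coded 2): per-patient nucleus counts, class-conditional
nuclear morphology and stain colour, exponential survival with independent
uniform censoring, and clinical/CNV/SNV/mRNA tables keyed by an opaque patient
barcode.  Nuclei are rendered as filled ellipses so that area, perimeter and
eccentricity have analytically known values for oracle tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import panels

__all__ = [
    "CohortSpec",
    "SyntheticPatient",
    "RenderResult",
    "generate_cohort",
    "render_tile",
    "sample_feature_rows",
    "write_cohort",
]

_SEXES = ("Male", "Female")
_RACES = (
    "American Indian or Alaska native", "Asian",
    "Black or African American", "White",
)
_T = ("T1", "T2", "T3", "T4", "TX")
_N = ("N0", "N1", "N2", "N3", "NX")
_M = ("M0", "M1", "MX")
_STAGES = ("Stage I", "Stage II", "Stage III", "Stage IV")

_NONSYN = (
    "Missense", "Nonsense", "Nonstop", "Translation_Start_Site",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Splice_Site",
)
_SYN = (
    "3'UTR", "5'UTR", "3'Flank", "5'Flank", "Silent", "Intron", "IGR",
    "RNA", "Splice region",
)


class ConfigurationError(ValueError):
    """Raised when a cohort specification violates its invariants."""


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic two-class cohort.

    Defaults emulate the reference cohort: 525 class-1 (LUAD) and 727 class-2
    (LUSC) patients; per-patient nucleus counts with a median near 200 (gamma–
    Poisson); exponential overall-survival times with class-specific rates and
    independent uniform censoring over an 8-year follow-up window.

    ``class_effect`` plants between-class mean shifts, keyed by:
    ``"area"`` (multiplicative shift of mean ellipse axis length, class 2 vs 1),
    ``"eccentricity"`` (additive shift of axis-ratio), ``"color"`` (additive
    RGB shift of the stain colour, 8-bit units), and ``"expression"`` (additive
    shift, in SDs, of the first ``n_effect_genes`` mRNA values).
    """

    n_patients_class1: int = 525
    n_patients_class2: int = 727
    nuclei_mean: float = 210.0
    nuclei_dispersion: float = 5.0
    tile_size: int = 128
    class_effect: dict[str, float] = field(default_factory=dict)
    n_effect_genes: int = 4
    event_rate_class1: float = np.log(2) / 1500.0  # per day; median OS ~4.1 y
    event_rate_class2: float = np.log(2) / 1100.0  # class 2 worse, ~3.0 y
    censoring_window_days: float = 2920.0
    censoring_rate: float = 1.0  # fraction of patients with a censoring draw
    noise_sd: float = 6.0
    stain_shift: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients_class1 <= 0 or self.n_patients_class2 <= 0:
            raise ConfigurationError("patient counts must be positive")
        if self.tile_size < 64:
            raise ConfigurationError("tile_size must be >= 64")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ConfigurationError("censoring_rate must lie in [0, 1]")
        if self.nuclei_mean <= 0 or self.nuclei_dispersion <= 0:
            raise ConfigurationError("nucleus-count distribution parameters must be positive")
        if min(self.event_rate_class1, self.event_rate_class2) <= 0:
            raise ConfigurationError("event rates must be positive")


@dataclass
class SyntheticPatient:
    """One simulated patient: labels, raw tables and rendering parameters."""

    patient_id: str
    subtype: int  # 1 = LUAD-like, 2 = LUSC-like
    os_time: float  # days
    css: str  # "alive" | "dead"
    clinical_raw: dict[str, object]
    cnv_amplitudes: dict[str, float]
    snv_classes: dict[str, str]
    expression: dict[str, float]
    n_nuclei: int
    mean_axis: float  # mean semi-major axis, px
    axis_ratio: float  # semi-minor / semi-major in (0, 1]
    stain_rgb: tuple[float, float, float]

    def to_raw(self) -> dict[str, object]:
        """Flatten into the raw-record mapping consumed by table assembly."""
        row: dict[str, object] = {"patient_id": self.patient_id,
                                  "subtype": self.subtype,
                                  "os_time": self.os_time, "css": self.css}
        row.update(self.clinical_raw)
        for g, v in self.cnv_amplitudes.items():
            row[f"cnv_{g}"] = v
        for g, v in self.snv_classes.items():
            row[f"snv_{g}"] = v
        for g, v in self.expression.items():
            row[f"mrna_{g}"] = v
        return row


def generate_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Draw a full cohort according to ``spec``; reproducible given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    eff = spec.class_effect
    patients: list[SyntheticPatient] = []
    counter = 0
    for subtype, n in ((1, spec.n_patients_class1), (2, spec.n_patients_class2)):
        rate = spec.event_rate_class1 if subtype == 1 else spec.event_rate_class2
        for _ in range(n):
            counter += 1
            pid = f"SYN-{subtype}-{counter:04d}"
            # survival: exponential event time, independent uniform censoring
            t_event = rng.exponential(1.0 / rate)
            if rng.random() < spec.censoring_rate:
                t_cens = rng.uniform(0.0, spec.censoring_window_days)
            else:
                t_cens = np.inf
            if t_event <= t_cens:
                os_time, css = t_event, "dead"
            else:
                os_time, css = t_cens, "alive"

            clinical_raw = {
                "sex": rng.choice(_SEXES),
                "race": rng.choice(_RACES) if rng.random() > 0.1 else None,
                "age_at_diagnosis": float(np.clip(rng.normal(66, 9), 35, 90)),
                "T": rng.choice(_T, p=(0.3, 0.45, 0.15, 0.07, 0.03)),
                "N": rng.choice(_N, p=(0.55, 0.2, 0.18, 0.04, 0.03)),
                "M": rng.choice(_M, p=(0.9, 0.05, 0.05)),
                "stage": rng.choice(_STAGES, p=(0.45, 0.3, 0.2, 0.05)),
            }

            shift = 1.0 if subtype == 1 else 1.0 + eff.get("area", 0.0)
            mean_axis = max(3.0, rng.normal(8.0, 1.0) * shift)
            ratio = np.clip(
                rng.normal(0.75, 0.08)
                - (eff.get("eccentricity", 0.0) if subtype == 2 else 0.0),
                0.15, 1.0)
            color_shift = eff.get("color", 0.0) if subtype == 2 else 0.0
            stain = (
                float(np.clip(rng.normal(120, 10) + color_shift, 0, 255)),
                float(np.clip(rng.normal(60, 8) + color_shift, 0, 255)),
                float(np.clip(rng.normal(150, 10) + color_shift, 0, 255)),
            )
            n_nuclei = int(rng.negative_binomial(
                spec.nuclei_dispersion,
                spec.nuclei_dispersion / (spec.nuclei_dispersion + spec.nuclei_mean)))
            n_nuclei = max(1, n_nuclei)

            expr_shift = eff.get("expression", 0.0) if subtype == 2 else 0.0
            expression = {}
            for i, g in enumerate(panels.GENES):
                mu = 5.0 + (i % 7)  # gene-specific baseline, log2-TPM-like scale
                x = rng.normal(mu, 1.0)
                if i < spec.n_effect_genes:
                    x += expr_shift
                expression[g] = float(x)
            cnv = {g: float(max(0.0, rng.gamma(1.2, 0.3))) for g in panels.GENES}
            snv = {}
            p_nonsyn = 0.35
            for g in panels.GENES:
                if rng.random() < p_nonsyn:
                    snv[g] = str(rng.choice(_NONSYN))
                else:
                    snv[g] = str(rng.choice(_SYN))

            patients.append(SyntheticPatient(
                patient_id=pid, subtype=subtype, os_time=float(os_time), css=css,
                clinical_raw=clinical_raw, cnv_amplitudes=cnv, snv_classes=snv,
                expression=expression, n_nuclei=n_nuclei, mean_axis=float(mean_axis),
                axis_ratio=float(ratio), stain_rgb=stain))
    return patients


@dataclass
class RenderResult:
    """A rendered tile with its ground truth.

    ``instances`` carry the true centre, semi-axes, orientation and colour of
    every nucleus actually placed; ``requested``/``placed`` record partial
    placement when the non-overlap policy could not fit all nuclei.
    """

    tile: np.ndarray  # H×W×3 uint8
    mask: np.ndarray  # H×W uint8 in {0,1}
    instances: list[dict]
    requested: int
    placed: int


def render_tile(patient: SyntheticPatient, n_nuclei: int, seed: int,
                tile_size: int = 128, noise_sd: float = 6.0,
                stain_shift: float = 12.0, max_attempts: int = 200,
                ) -> RenderResult:
    """Render a tile of elliptical nuclei on a light eosin-like background.

    Nuclei are filled ellipses with class-conditional axis lengths, orientation
    and stain colour; the mask is the exact union of the rendered nuclei and
    overlap is disallowed (rejection sampling with a 1-px margin).  If a
    nucleus cannot be placed within ``max_attempts`` draws, placement stops and
    the shortfall is reported via ``placed`` < ``requested``.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    rng = np.random.default_rng(seed)
    h = w = tile_size
    # background: pale pink with a per-tile stain shift and pixel noise
    base = np.array([235.0, 215.0, 225.0]) + rng.uniform(-stain_shift, stain_shift, 3)
    tile = np.clip(base[None, None, :] + rng.normal(0.0, noise_sd, (h, w, 3)),
                   0, 255)
    mask = np.zeros((h, w), dtype=np.uint8)
    occupied = np.zeros((h, w), dtype=bool)
    instances: list[dict] = []

    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_nuclei):
        placed = False
        for _attempt in range(max_attempts):
            a = max(2.5, rng.normal(patient.mean_axis, 1.2))
            b = max(2.0, a * np.clip(rng.normal(patient.axis_ratio, 0.05), 0.15, 1.0))
            theta = rng.uniform(0, np.pi)
            margin = a + 2
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            dil = (u / (a + 1.5)) ** 2 + (v / (b + 1.5)) ** 2 <= 1.0
            if not inside.any() or (occupied & dil).any():
                continue
            color = np.clip(np.asarray(patient.stain_rgb)
                            + rng.normal(0, 4, 3), 0, 255)
            noise = rng.normal(0.0, noise_sd, (int(inside.sum()), 3))
            tile[inside] = np.clip(color[None, :] + noise, 0, 255)
            mask[inside] = 1
            occupied |= dil
            instances.append({
                "center": (float(cy), float(cx)),
                "axes": (float(a), float(b)),
                "orientation": float(theta),
                "color": tuple(float(c) for c in color),
                "area_px": int(inside.sum()),
            })
            placed = True
            break
        if not placed:
            break
    return RenderResult(tile=tile.astype(np.uint8), mask=mask,
                        instances=instances, requested=n_nuclei,
                        placed=len(instances))


def sample_feature_rows(cohort: list[SyntheticPatient], seed: int = 0,
                        rows_per_patient: int | None = None,
                        effects: dict[str, float] | None = None,
                        patient_sd: float = 0.3, noise_sd: float = 1.0):
    """Draw per-nucleus feature rows directly, without rendering images.

    A fast stand-in for the render→segment→measure path: every feature column
    is Gaussian with unit nucleus-level noise, a per-patient random intercept
    (``patient_sd``) modelling within-patient correlation, and a between-class
    mean shift of ``effects[column]`` noise-SD units added for class-2
    patients.  ``rows_per_patient=None`` uses each patient's drawn nucleus
    count.  Returns a DataFrame with patient_id, tile_id, label and the 20
    feature columns.
    """
    import pandas as pd

    from .nucfeat import FEATURE_COLUMNS

    effects = effects or {}
    unknown = set(effects) - set(FEATURE_COLUMNS)
    if unknown:
        raise ConfigurationError(f"unknown feature columns in effects: {unknown}")
    rng = np.random.default_rng(seed)
    blocks = []
    for p in cohort:
        n = rows_per_patient if rows_per_patient is not None else p.n_nuclei
        intercepts = rng.normal(0.0, patient_sd, len(FEATURE_COLUMNS))
        data = rng.normal(0.0, noise_sd, (n, len(FEATURE_COLUMNS))) + intercepts
        if p.subtype == 2:
            for j, col in enumerate(FEATURE_COLUMNS):
                data[:, j] += effects.get(col, 0.0)
        df = pd.DataFrame(data, columns=list(FEATURE_COLUMNS))
        df.insert(0, "patient_id", p.patient_id)
        df.insert(1, "tile_id", "t0")
        df.insert(2, "label", np.arange(1, n + 1))
        blocks.append(df)
    return pd.concat(blocks, ignore_index=True)


def _labelme_annotation(result: RenderResult, image_path: str) -> dict:
    """LabelMe-style polygon annotation approximating each rendered ellipse."""
    shapes = []
    for inst in result.instances:
        cy, cx = inst["center"]
        a, b = inst["axes"]
        th = inst["orientation"]
        t = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        xs = cx + a * np.cos(t) * np.cos(th) - b * np.sin(t) * np.sin(th)
        ys = cy + a * np.cos(t) * np.sin(th) + b * np.sin(t) * np.cos(th)
        shapes.append({
            "label": "nucleus",
            "points": [[float(x), float(y)] for x, y in zip(xs, ys)],
            "shape_type": "polygon",
        })
    return {"version": "5.3.1", "imagePath": image_path,
            "imageHeight": int(result.tile.shape[0]),
            "imageWidth": int(result.tile.shape[1]), "shapes": shapes}


def write_cohort(cohort: list[SyntheticPatient], outdir: str | Path,
                 tiles_per_patient: int = 1, nuclei_per_tile: int | None = None,
                 tile_size: int = 128, seed: int = 0) -> Path:
    """Write tiles (PNG), masks (PNG), LabelMe JSON and TSV tables; return manifest path."""
    import imageio.v3 as iio
    import pandas as pd

    out = Path(outdir)
    (out / "tiles").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)
    manifest: dict[str, object] = {"patients": [], "tables": {}, "tiles": []}

    for i, p in enumerate(cohort):
        manifest["patients"].append(p.patient_id)
        for t in range(tiles_per_patient):
            n = nuclei_per_tile if nuclei_per_tile is not None else max(
                1, p.n_nuclei // tiles_per_patient)
            tile_seed = (seed * 1000003 + i * 1009 + t) % (2**31)
            res = render_tile(p, n, seed=tile_seed, tile_size=tile_size)
            stem = f"{p.patient_id}_t{t}"
            iio.imwrite(out / "tiles" / f"{stem}.png", res.tile)
            iio.imwrite(out / "masks" / f"{stem}.png", res.mask * 255)
            ann = _labelme_annotation(res, f"../tiles/{stem}.png")
            (out / "annotations" / f"{stem}.json").write_text(json.dumps(ann))
            manifest["tiles"].append({
                "patient_id": p.patient_id, "tile": f"tiles/{stem}.png",
                "mask": f"masks/{stem}.png",
                "annotation": f"annotations/{stem}.json",
                "requested": res.requested, "placed": res.placed})

    clin = pd.DataFrame([{"patient_id": p.patient_id, "subtype": p.subtype,
                          "os_time": p.os_time, "css": p.css, **p.clinical_raw}
                         for p in cohort])
    cnv = pd.DataFrame([{"patient_id": p.patient_id, "gene": g, "t": v}
                        for p in cohort for g, v in p.cnv_amplitudes.items()])
    mrna = pd.DataFrame({"gene": list(panels.GENES),
                         **{p.patient_id: [p.expression[g] for g in panels.GENES]
                            for p in cohort}})
    snv_rows = [{"Tumor_Sample_Barcode": p.patient_id, "Hugo_Symbol": g,
                 "Variant_Classification": c}
                for p in cohort for g, c in p.snv_classes.items()]
    snv = pd.DataFrame(snv_rows)
    for name, df in (("clinical", clin), ("cnv", cnv), ("snv", snv), ("mrna", mrna)):
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest["tables"][name] = f"{name}.tsv"

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path
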