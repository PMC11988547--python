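"""Factor encoding, survival labelling, balancing, patient-level splitting, merging.

Clinical strings are mapped to small integers (sex 1/2; race 0-4 with 0 for
unreported; T/N 1-5 with X as 5; M 1/2/5; stage 1-4).  Survival at a horizon is
a three-class label: 0 unknown (alive, followed up for less than the horizon),
1 death before the horizon, 2 survival past the horizon.  CNV amplitudes t are
discretised to 0 (t <= 0.1), 1 (0.1 < t <= 0.9), 2 (t > 0.9); SNV variant
classifications are binarised to non-synonymous (1) vs synonymous (0) over a
closed vocabulary.

Per-nucleus rows are merged with patient factors on the patient barcode,
balanced to exactly 200 rows per patient (random under-sampling above, random
duplication below), and partitioned 60/20/20 at patient level, stratified by
subtype by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import panels
from .nucfeat import FEATURE_COLUMNS

__all__ = [
    "ValidationError",
    "PatientRecord",
    "AssembledDataset",
    "encode_clinical",
    "decode_clinical",
    "survival_label",
    "cnv_code",
    "snv_code",
    "balance_patient",
    "split_patients",
    "build_patient_table",
    "assemble",
    "load_tables",
    "CLINICAL_COLUMNS",
    "HORIZONS_DAYS",
]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when an input value falls outside its closed vocabulary."""


SEX_CODES = {"male": 1, "female": 2}
RACE_CODES = {
    "american indian or alaska native": 1,
    "asian": 2,
    "black or african american": 3,
    "white": 4,
}
T_CODES = {"t1": 1, "t2": 2, "t3": 3, "t4": 4, "tx": 5}
N_CODES = {"n0": 1, "n1": 2, "n2": 3, "n3": 4, "nx": 5}
M_CODES = {"m0": 1, "m1": 2, "mx": 5}
STAGE_CODES = {"stage i": 1, "stage ii": 2, "stage iii": 3, "stage iv": 4}

#: encoded clinical factor columns, in table order
CLINICAL_COLUMNS = ("Gender", "Race", "Age_at_diagnosis", "T", "N", "M", "Stage")

#: 1/2/3-year horizons in days
HORIZONS_DAYS = {1: 365, 2: 730, 3: 1095}

_NON_SYNONYMOUS = {
    "missense", "nonsense", "nonstop", "translation_start_site",
    "frame_shift_del", "frame_shift_ins", "in_frame_del", "in_frame_ins",
    "splice_site",
}
_SYNONYMOUS = {
    "3'utr", "5'utr", "3'flank", "5'flank", "silent", "intron", "igr",
    "rna", "splice region",
}


def _lookup(field_name: str, value, table: dict[str, int]) -> int:
    key = str(value).strip().lower()
    if key not in table:
        raise ValidationError(f"unmapped {field_name} value: {value!r}")
    return table[key]


def encode_clinical(raw: dict) -> dict[str, float]:
    """Encode a raw clinical record into the numeric factor columns.

    Expects keys sex, race, age_at_diagnosis, T, N, M, stage (case-insensitive
    values).  A missing/unmapped race encodes as 0 (unreported); an unmapped
    value in any other field raises :class:`ValidationError`.
    """
    race_raw = raw.get("race")
    if race_raw is None or (isinstance(race_raw, float) and math.isnan(race_raw)):
        race = 0
    else:
        race = RACE_CODES.get(str(race_raw).strip().lower(), 0)
    return {
        "Gender": _lookup("sex", raw["sex"], SEX_CODES),
        "Race": race,
        "Age_at_diagnosis": float(raw["age_at_diagnosis"]),
        "T": _lookup("T", raw["T"], T_CODES),
        "N": _lookup("N", raw["N"], N_CODES),
        "M": _lookup("M", raw["M"], M_CODES),
        "Stage": _lookup("stage", raw["stage"], STAGE_CODES),
    }


_DECODE = {
    "Gender": {v: k.capitalize() for k, v in SEX_CODES.items()},
    "Race": {0: "Unreported", 1: "American Indian or Alaska native",
             2: "Asian", 3: "Black or African American", 4: "White"},
    "T": {v: k.upper() for k, v in T_CODES.items()},
    "N": {v: k.upper() for k, v in N_CODES.items()},
    "M": {v: k.upper() for k, v in M_CODES.items()},
    "Stage": {1: "Stage I", 2: "Stage II", 3: "Stage III", 4: "Stage IV"},
}


def decode_clinical(encoded: dict) -> dict:
    """Inverse of :func:`encode_clinical` on the categorical fields."""
    out = {}
    for col, value in encoded.items():
        if col in _DECODE:
            out[col] = _DECODE[col][int(value)]
        else:
            out[col] = value
    return out


def survival_label(css: str, os_time: float, horizon: float) -> int:
    """Three-class survival status at a horizon (days).

    1 = death before the horizon; 2 = followed up past the horizon (alive or
    dead later); 0 = unknown (alive at last follow-up, which precedes the
    horizon).
    """
    if os_time < 0:
        raise ValidationError(f"negative os_time: {os_time}")
    if css not in ("alive", "dead"):
        raise ValidationError(f"css must be 'alive' or 'dead', got {css!r}")
    if os_time >= horizon:
        return 2
    return 1 if css == "dead" else 0


def cnv_code(t: float) -> int:
    """Discretise a copy-number amplitude; boundaries go to the lower class."""
    if t < 0:
        raise ValidationError(f"negative CNV amplitude: {t}")
    if t <= 0.1:
        return 0
    if t <= 0.9:
        return 1
    return 2


def snv_code(variant_classification: str) -> int:
    """1 for non-synonymous variant classes, 0 for synonymous; closed vocabulary."""
    key = str(variant_classification).strip().lower().replace("′", "'")
    if key in _NON_SYNONYMOUS:
        return 1
    if key in _SYNONYMOUS:
        return 0
    raise ValidationError(
        f"unlisted variant classification: {variant_classification!r}")


@dataclass
class PatientRecord:
    """Encoded clinical + genetic factors and labels for one patient."""

    patient_id: str
    clinical: dict[str, float]
    subtype: int
    y1: int
    y2: int
    y3: int
    cnv: dict[str, int] = field(default_factory=dict)
    snv: dict[str, int] = field(default_factory=dict)
    mrna: dict[str, float] = field(default_factory=dict)


def build_patient_table(records, cnv_panel=panels.CNV_PANEL,
                        snv_panel=panels.SNV_PANEL,
                        mrna_panel=panels.MRNA_PANEL) -> pd.DataFrame:
    """Encode raw per-patient records into the patient factor table.

    ``records`` is an iterable of mappings with keys: patient_id, subtype,
    os_time, css, the raw clinical fields, and cnv_<gene> (amplitude t),
    snv_<gene> (variant classification) and mrna_<gene> values for the
    configured panels.  Returns one row per patient, indexed by patient_id.
    """
    rows = []
    for raw in records:
        row: dict[str, object] = {"patient_id": raw["patient_id"],
                                  "Type": int(raw["subtype"])}
        row.update(encode_clinical(raw))
        for year, days in HORIZONS_DAYS.items():
            row[f"y{year}"] = survival_label(raw["css"], float(raw["os_time"]), days)
        for g in cnv_panel:
            row[f"cnv_{g}"] = cnv_code(float(raw[f"cnv_{g}"]))
        for g in snv_panel:
            row[f"snv_{g}"] = snv_code(raw[f"snv_{g}"])
        for g in mrna_panel:
            row[f"mrna_{g}"] = float(raw[f"mrna_{g}"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def balance_patient(rows: pd.DataFrame, target: int = 200,
                    seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Standardise one patient's nucleus rows to exactly ``target`` rows.

    More than ``target`` rows: a uniform random subset without replacement.
    Fewer: all originals plus uniform random duplicates.  Deterministic given
    the seed.
    """
    if len(rows) == 0:
        raise ValidationError("cannot balance a patient with zero rows")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = len(rows)
    if n == target:
        return rows.reset_index(drop=True)
    if n > target:
        idx = rng.choice(n, size=target, replace=False)
    else:
        extra = rng.choice(n, size=target - n, replace=True)
        idx = np.concatenate([np.arange(n), extra])
    return rows.iloc[idx].reset_index(drop=True)


def split_patients(patient_ids, subtypes=None,
                   fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                   stratify: bool = True, seed: int = 0) -> dict[str, str]:
    """Patient-level train/validation/test partition.

    With stratification each subtype is split independently.  Within a stratum
    of size n, validation and test sizes are round-half-up of f_val*n and
    f_test*n and train takes the remainder; this reproduces the published
    315/437 training and 105+145 held-out stratum sizes for 525+727 patients.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    patient_ids = list(patient_ids)
    if subtypes is None or not stratify:
        strata = {None: patient_ids}
    else:
        subtypes = list(subtypes)
        strata = {}
        for pid, st in zip(patient_ids, subtypes):
            strata.setdefault(st, []).append(pid)
    rng = np.random.default_rng(seed)
    partition: dict[str, str] = {}
    for key in sorted(strata, key=str):
        ids = sorted(strata[key])
        n = len(ids)
        if n < 3:
            raise ValueError(f"stratum {key!r} has fewer than 3 patients")
        n_val = int(math.floor(fractions[1] * n + 0.5))
        n_test = int(math.floor(fractions[2] * n + 0.5))
        n_train = n - n_val - n_test
        order = rng.permutation(n)
        for j, k in enumerate(order):
            if j < n_train:
                partition[ids[k]] = "train"
            elif j < n_train + n_val:
                partition[ids[k]] = "validation"
            else:
                partition[ids[k]] = "test"
    return partition


@dataclass
class AssembledDataset:
    """Balanced per-nucleus rows joined with patient factors, split by patient."""

    rows: pd.DataFrame
    partition: dict[str, str]
    feature_columns: list[str]
    label_column: str
    task: str

    def subset(self, part: str) -> pd.DataFrame:
        ids = {p for p, v in self.partition.items() if v == part}
        return self.rows[self.rows["patient_id"].isin(ids)]

    def design(self, part: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.subset(part)
        return (sub[self.feature_columns].to_numpy(float),
                sub[self.label_column].to_numpy())


def assemble(features: pd.DataFrame, patients: pd.DataFrame, task: str,
             target: int = 200,
             fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
             stratify: bool = True, seed: int = 0,
             cnv_panel=panels.CNV_PANEL, snv_panel=panels.SNV_PANEL,
             mrna_panel=panels.MRNA_PANEL) -> AssembledDataset:
    """Merge nuclear features with patient factors and build the task dataset.

    ``task`` is "subtype" (design = 20 nuclear + mRNA factors; 46 columns with
    the default 26-gene panel) or "os1"/"os2"/"os3" (all nuclear + clinical +
    CNV + SNV + mRNA factors; 95 columns with the default panels).  Each
    retained patient contributes exactly ``target`` rows; the partition is
    patient-level, stratified by subtype by default.
    """
    if task == "subtype":
        label = "Type"
        feature_columns = list(FEATURE_COLUMNS) + [f"mrna_{g}" for g in mrna_panel]
    elif task in ("os1", "os2", "os3"):
        label = f"y{task[-1]}"
        feature_columns = (list(FEATURE_COLUMNS) + list(CLINICAL_COLUMNS)
                           + [f"cnv_{g}" for g in cnv_panel]
                           + [f"snv_{g}" for g in snv_panel]
                           + [f"mrna_{g}" for g in mrna_panel])
    else:
        raise ValueError(f"unknown task {task!r}")

    known = set(patients.index)
    have = set(features["patient_id"].unique())
    missing = have - known
    if missing:
        logger.warning("dropping %d patients with features but no record",
                       len(missing))
    usable = sorted(have & known)
    if not usable:
        raise ValidationError("no patients with both features and records")

    rng = np.random.default_rng(seed)
    groups = dict(tuple(features.groupby("patient_id", sort=False)))
    balanced = [balance_patient(groups[pid], target=target, seed=rng)
                for pid in usable]
    rows = pd.concat(balanced, ignore_index=True)
    rows = rows.merge(patients.reset_index(), on="patient_id", how="left")

    subtypes = [int(patients.loc[pid, "Type"]) for pid in usable]
    partition = split_patients(usable, subtypes=subtypes, fractions=fractions,
                               stratify=stratify, seed=seed)
    return AssembledDataset(rows=rows, partition=partition,
                            feature_columns=feature_columns,
                            label_column=label, task=task)


def load_tables(clinical_path: str | Path, cnv_path: str | Path,
                snv_path: str | Path, mrna_path: str | Path,
                cnv_panel=panels.CNV_PANEL, snv_panel=panels.SNV_PANEL,
                mrna_panel=panels.MRNA_PANEL) -> pd.DataFrame:
    """Read the four on-disk tables and return the encoded patient table.

    Formats: clinical TSV (one row per patient: patient_id, subtype, os_time,
    css, sex, race, age_at_diagnosis, T, N, M, stage); CNV TSV in long form
    (patient_id, gene, t); SNV TSV in MAF style (Tumor_Sample_Barcode,
    Hugo_Symbol, Variant_Classification); mRNA TSV as gene x patient matrix
    (first column ``gene``).  A gene with no SNV row for a patient counts as 0.
    """
    clin = pd.read_csv(clinical_path, sep="\t")
    cnv = pd.read_csv(cnv_path, sep="\t")
    snv = pd.read_csv(snv_path, sep="\t")
    mrna = pd.read_csv(mrna_path, sep="\t").set_index("gene")

    cnv_wide = cnv.pivot_table(index="patient_id", columns="gene", values="t",
                               aggfunc="max")
    snv_codes: dict[tuple[str, str], int] = {}
    for _, r in snv.iterrows():
        key = (r["Tumor_Sample_Barcode"], r["Hugo_Symbol"])
        code = snv_code(r["Variant_Classification"])
        snv_codes[key] = max(snv_codes.get(key, 0), code)

    records = []
    for _, row in clin.iterrows():
        pid = row["patient_id"]
        raw = dict(row)
        for g in cnv_panel:
            raw[f"cnv_{g}"] = float(cnv_wide.loc[pid, g])
        for g in snv_panel:
            # re-encode below expects a classification string; use a sentinel
            raw[f"snv_{g}"] = "Missense" if snv_codes.get((pid, g), 0) else "Silent"
        for g in mrna_panel:
            raw[f"mrna_{g}"] = float(mrna.loc[g, pid])
        records.append(raw)
    return build_patient_table(records, cnv_panel=cnv_panel,
                               snv_panel=snv_panel, mrna_panel=mrna_panel)
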