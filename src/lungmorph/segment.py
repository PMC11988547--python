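"""Nucleus segmentation, instance labelling and the Otsu-based quality filter.

Segmentation is a training/inference contract around a small U-shaped
encoder–decoder (:mod:`lungmorph.unet`).  Predicted probability maps are
binarised and labelled into 8-connected instances; each instance carries its
area ``A`` (pixel count), perimeter ``P`` (outer-boundary polygon arc length,
diagonal steps counted as sqrt(2)) and compactness ``C = P^2 / A``.

The per-image quality filter computes adaptive thresholds on the area and
compactness histograms with Otsu's method (between-class variance
maximisation) and removes instances with area strictly below the area
threshold or compactness strictly above the compactness threshold — the
fragmented and ragged false detections, respectively.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.measure import label as cc_label

from .unet import UNet, UNetConfig

__all__ = [
    "NucleusInstance",
    "FilterResult",
    "DegenerateInputError",
    "otsu_threshold",
    "binarize_and_label",
    "filter_instances",
    "boundary_perimeter",
    "rasterize_labelme",
    "train_segmenter",
    "dice_coefficient",
    "UNet",
    "UNetConfig",
]

logger = logging.getLogger(__name__)

# clockwise Moore neighbourhood starting north, (dy, dx)
_NBRS = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


class DegenerateInputError(ValueError):
    """Raised when a threshold cannot be derived (e.g. all values identical)."""


@dataclass
class NucleusInstance:
    """One 8-connected foreground region with its quality descriptors."""

    label: int
    coords: np.ndarray  # (n, 2) array of (row, col) pixel coordinates
    area: float
    perimeter: float
    compactness: float

    def silhouette(self, pad: int = 0) -> tuple[np.ndarray, tuple[int, int]]:
        """Binary bounding-box mask of the instance and its (row, col) offset."""
        r0, c0 = self.coords.min(axis=0)
        r1, c1 = self.coords.max(axis=0)
        mask = np.zeros((r1 - r0 + 1 + 2 * pad, c1 - c0 + 1 + 2 * pad), dtype=np.uint8)
        mask[self.coords[:, 0] - r0 + pad, self.coords[:, 1] - c0 + pad] = 1
        return mask, (int(r0 - pad), int(c0 - pad))


def _trace_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Moore-neighbour boundary trace (Jacob's stopping criterion).

    Returns the closed sequence of outer-boundary pixel centres, clockwise,
    starting at the topmost-leftmost foreground pixel.
    """
    h, w = mask.shape
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask")
    i = np.argmin(ys * w + xs)
    start = (int(ys[i]), int(xs[i]))
    first_b = (start[0], start[1] - 1)  # west of start is background
    boundary = [start]
    cur, b = start, first_b
    seen = {(cur, b)}
    while True:
        k0 = _NBRS.index((b[0] - cur[0], b[1] - cur[1]))
        nxt = None
        prev = b
        for k in range(1, 9):
            d = _NBRS[(k0 + k) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if 0 <= cand[0] < h and 0 <= cand[1] < w and mask[cand]:
                nxt = cand
                break
            prev = cand
        if nxt is None:  # isolated single pixel
            return boundary
        cur, b = nxt, prev
        # the walk is a deterministic map on (pixel, backtrack) states, so the
        # first repeated state closes the boundary cycle
        if (cur, b) in seen:
            return boundary
        seen.add((cur, b))
        boundary.append(cur)


def boundary_perimeter(mask: np.ndarray) -> float:
    """Outer-boundary polygon arc length of a single connected region.

    Axis steps contribute 1, diagonal steps sqrt(2).  A single-pixel region
    has no traversable boundary polygon; its perimeter is defined as 1.0.
    """
    pts = _trace_boundary(np.asarray(mask, dtype=bool))
    if len(pts) == 1:
        return 1.0
    arr = np.array(pts + [pts[0]], dtype=float)
    steps = np.diff(arr, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def _make_instance(label_id: int, coords: np.ndarray) -> NucleusInstance:
    r0, c0 = coords.min(axis=0)
    r1, c1 = coords.max(axis=0)
    m = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    m[coords[:, 0] - r0, coords[:, 1] - c0] = True
    area = float(coords.shape[0])
    perim = boundary_perimeter(m)
    return NucleusInstance(label=int(label_id), coords=coords, area=area,
                           perimeter=perim, compactness=perim ** 2 / area)


def binarize_and_label(prob_map: np.ndarray, threshold: float = 0.5
                       ) -> list[NucleusInstance]:
    """Threshold a probability map and label 8-connected foreground regions."""
    prob = np.asarray(prob_map, dtype=float)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    fg = prob >= threshold
    labels = cc_label(fg, connectivity=2)
    out = []
    for lab in range(1, labels.max() + 1):
        coords = np.argwhere(labels == lab)
        out.append(_make_instance(lab, coords))
    return out


def otsu_threshold(values, n_bins: int = 64) -> float:
    """Otsu's threshold on a list of scalar feature values.

    The histogram uses ``n_bins`` equal-width bins spanning [min, max]; the
    returned value is the interior bin edge maximising the between-class
    variance (equivalently minimising within-class variance).  Ties go to the
    smallest edge; splits moving across empty bins leave the criterion
    mathematically unchanged, so ties are detected with a small relative
    tolerance rather than bit equality.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2 or np.ptp(vals) == 0:
        raise DegenerateInputError("need at least two distinct values")
    hist, edges = np.histogram(vals, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    w0 = np.cumsum(p)[:-1]                       # class 0: bins < split
    w1 = 1.0 - w0
    cum_mu = np.cumsum(p * centers)[:-1]
    total_mu = (p * centers).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mu / w0
        mu1 = (total_mu - cum_mu) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-np.inf)
    smax = sigma_b.max()
    k = int(np.argmax(sigma_b >= smax - 1e-9 * max(1.0, abs(smax))))
    return float(edges[k + 1])


@dataclass
class FilterResult:
    kept: list[NucleusInstance]
    removed: list[NucleusInstance]
    area_threshold: float | None
    compactness_threshold: float | None


def filter_instances(instances: list[NucleusInstance], n_bins: int = 64
                     ) -> FilterResult:
    """Per-image adaptive quality filter.

    Removes instances with ``area < area_threshold`` or
    ``compactness > compactness_threshold`` (strict comparisons; boundary-equal
    instances are kept), where each threshold is Otsu's threshold on that
    feature's histogram for this image.  If a feature is degenerate (all values
    identical) its criterion is skipped and logged; the other still applies.
    """
    if not instances:
        return FilterResult([], [], None, None)
    areas = [i.area for i in instances]
    comps = [i.compactness for i in instances]
    try:
        area_thr: float | None = otsu_threshold(areas, n_bins)
    except DegenerateInputError:
        logger.info("area criterion skipped: degenerate histogram")
        area_thr = None
    try:
        comp_thr: float | None = otsu_threshold(comps, n_bins)
    except DegenerateInputError:
        logger.info("compactness criterion skipped: degenerate histogram")
        comp_thr = None
    kept, removed = [], []
    for inst in instances:
        ok = True
        if area_thr is not None and inst.area < area_thr:
            ok = False
        if comp_thr is not None and inst.compactness > comp_thr:
            ok = False
        (kept if ok else removed).append(inst)
    return FilterResult(kept, removed, area_thr, comp_thr)


def rasterize_labelme(annotation: dict | str | Path,
                      shape: tuple[int, int] | None = None) -> np.ndarray:
    """Rasterise LabelMe-style polygon annotations to a binary mask.

    Vertices are in (x, y) pixel coordinates; each polygon is filled with a
    crossing (even–odd) point-in-polygon test and shapes are unioned.
    """
    if not isinstance(annotation, dict):
        annotation = json.loads(Path(annotation).read_text())
    if shape is None:
        shape = (annotation["imageHeight"], annotation["imageWidth"])
    mask = np.zeros(shape, dtype=np.uint8)
    for sh in annotation.get("shapes", []):
        pts = np.asarray(sh["points"], dtype=float)
        rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=shape)
        mask[rr, cc] = 1
    return mask


def train_segmenter(pairs, config: UNetConfig | None = None,
                    checkpoint: str | Path | None = None) -> UNet:
    """Train the U-shaped segmenter on (tile, mask) pairs.

    ``pairs`` is a sequence of (H×W×3 uint8 tile, H×W {0,1} mask) tuples, all
    of one size.  Deterministic given ``config.seed``; per-epoch training loss
    is recorded on the returned model's ``loss_history``.  If ``checkpoint`` is
    given, the trained weights are saved there (reloadable via ``UNet.load``).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one (tile, mask) pair")
    tiles, masks = [], []
    for tile, mask in pairs:
        tile = np.asarray(tile)
        mask = np.asarray(mask)
        if tile.shape[:2] != mask.shape:
            raise ValueError(
                f"tile {tile.shape[:2]} and mask {mask.shape} are misaligned")
        tiles.append(tile)
        masks.append((mask > 0).astype(np.float64))
    model = UNet(config)
    model.fit(np.stack(tiles), np.stack(masks))
    if checkpoint is not None:
        model.save(checkpoint)
    return model


def dice_coefficient(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice overlap 2|X∩Y| / (|X|+|Y|); 1.0 when both masks are empty."""
    a = np.asarray(pred_mask) > 0
    b = np.asarray(true_mask) > 0
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
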