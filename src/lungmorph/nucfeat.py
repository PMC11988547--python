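"""The 20 per-nucleus features: 6 colour, 12 morphology, 2 texture.

Colour features are the per-channel mean and population variance of the RGB
values inside the nucleus (computed on the histogram-matched tile).  Morphology
comprises area A, perimeter P, circularity 4*pi*A/P^2, compactness P^2/A,
eccentricity of the moment-equivalent ellipse, and the seven Hu moment
invariants of the binary silhouette.  Texture is the mean and population
variance of the diagonal-detail (cD) subband of a single-level 2-D discrete
wavelet transform of the masked grayscale nucleus patch.

Moment quantities follow the standard construction: geometric moments
m_pq = sum x^p y^q f(x,y), central moments about the centroid, normalised
central moments eta_pq = mu_pq / mu_00^gamma with gamma = (p+q)/2 + 1, and the
seven Hu combinations of the eta_pq.  Hu moments are computed on the binary
silhouette, making translation invariance exact and rotation/scale invariance
exact up to rasterisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .segment import NucleusInstance

__all__ = [
    "FEATURE_COLUMNS",
    "MomentSet",
    "color_stats",
    "shape_descriptors",
    "geometric_moments",
    "hu_moments",
    "wavelet_texture",
    "extract_features",
]

#: fixed feature order of the per-nucleus vector
FEATURE_COLUMNS: tuple[str, ...] = (
    "R_average", "G_average", "B_average", "R_var", "G_var", "B_var",
    "Area", "Perimeter", "Circularity", "Compactness", "Eccentric",
    "Hu0", "Hu1", "Hu2", "Hu3", "Hu4", "Hu5", "Hu6",
    "cD_average", "cD_var",
)


def color_stats(tile: np.ndarray, instance: NucleusInstance) -> tuple[float, ...]:
    """Per-channel mean and population variance over the instance's pixels.

    Returns (R_average, G_average, B_average, R_var, G_var, B_var).
    """
    px = np.asarray(tile)
    if instance.coords.shape[0] == 0:
        raise ValueError("instance has an empty pixel set")
    vals = px[instance.coords[:, 0], instance.coords[:, 1], :3].astype(float)
    means = vals.mean(axis=0)
    variances = vals.var(axis=0)  # population variance (divide by N)
    return (*means, *variances)


@dataclass
class MomentSet:
    """Geometric, central and normalised central moments up to order 3."""

    m: np.ndarray      # m[p, q] geometric moments
    mu: np.ndarray     # central moments
    eta: np.ndarray    # normalised central moments
    centroid: tuple[float, float]  # (x_bar, y_bar)


def geometric_moments(silhouette: np.ndarray, order: int = 3) -> MomentSet:
    """Moments of a binary silhouette f(x, y) in {0, 1}.

    x indexes columns, y indexes rows (image convention).  Vectorised over the
    pixel grid; equals the naive double-loop summation exactly.
    """
    f = np.asarray(silhouette, dtype=float)
    if f.sum() == 0:
        raise ValueError("empty silhouette")
    ys, xs = np.mgrid[0:f.shape[0], 0:f.shape[1]]
    xp = xs[None, ...] ** np.arange(order + 1)[:, None, None]
    yq = ys[None, ...] ** np.arange(order + 1)[:, None, None]
    m = np.einsum("pij,qij,ij->pq", xp, yq, f)
    xbar = m[1, 0] / m[0, 0]
    ybar = m[0, 1] / m[0, 0]
    xcp = (xs - xbar)[None, ...] ** np.arange(order + 1)[:, None, None]
    ycq = (ys - ybar)[None, ...] ** np.arange(order + 1)[:, None, None]
    mu = np.einsum("pij,qij,ij->pq", xcp, ycq, f)
    eta = np.zeros_like(mu)
    for p in range(order + 1):
        for q in range(order + 1):
            gamma = (p + q) / 2.0 + 1.0
            eta[p, q] = mu[p, q] / mu[0, 0] ** gamma
    return MomentSet(m=m, mu=mu, eta=eta, centroid=(float(xbar), float(ybar)))


def hu_moments(silhouette: np.ndarray) -> np.ndarray:
    """The seven Hu moment invariants of a binary silhouette.

    The silhouette is cropped to its bounding box first, which makes
    translation invariance bit-exact (a translated shape yields the identical
    cropped array, hence the identical floating-point summation).
    """
    s = np.asarray(silhouette)
    if s.sum() == 0:
        raise ValueError("empty silhouette")
    ys, xs = np.nonzero(s)
    s = s[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    eta = geometric_moments(s).eta
    n20, n02, n11 = eta[2, 0], eta[0, 2], eta[1, 1]
    n30, n03, n21, n12 = eta[3, 0], eta[0, 3], eta[2, 1], eta[1, 2]
    hu0 = n20 + n02
    hu1 = (n20 - n02) ** 2 + 4 * n11 ** 2
    hu2 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    hu3 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    hu4 = ((n30 - 3 * n12) * (n30 + n12)
           * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
           + (3 * n21 - n03) * (n21 + n03)
           * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2))
    hu5 = ((n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2)
           + 4 * n11 * (n30 + n12) * (n21 + n03))
    hu6 = ((3 * n21 - n03) * (n30 + n12)
           * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2)
           - (n30 - 3 * n12) * (n21 + n03)
           * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2))
    return np.array([hu0, hu1, hu2, hu3, hu4, hu5, hu6])


_MIN_AXIS = 1e-6


def shape_descriptors(instance: NucleusInstance
                      ) -> tuple[float, float, float, float, float]:
    """(A, P, Circularity, Compactness, Eccentricity) of one instance.

    Circularity = 4*pi*A/P^2 (1 for a disc), Compactness = P^2/A (minimal at
    4*pi for a disc).  Eccentricity sqrt(a^2 - b^2)/a uses the semi-axes
    a >= b of the ellipse with the same second central moments as the binary
    silhouette; for degenerate (line-like) regions b is clamped at a small
    positive value.
    """
    a_px = instance.area
    p_len = instance.perimeter
    circularity = 4.0 * np.pi * a_px / p_len ** 2
    compactness = p_len ** 2 / a_px
    mask, _ = instance.silhouette()
    ms = geometric_moments(mask, order=2)
    mu00 = ms.mu[0, 0]
    cov = np.array([[ms.mu[2, 0], ms.mu[1, 1]],
                    [ms.mu[1, 1], ms.mu[0, 2]]]) / mu00
    lam = np.linalg.eigvalsh(cov)  # ascending
    lam1 = max(lam[1], _MIN_AXIS)
    lam2 = max(lam[0], _MIN_AXIS)
    ecc = float(np.sqrt(max(0.0, 1.0 - lam2 / lam1)))
    return float(a_px), float(p_len), float(circularity), float(compactness), ecc


def _grayscale(tile: np.ndarray) -> np.ndarray:
    """Luminance grayscale on the 8-bit scale (Rec. 709 weights)."""
    px = np.asarray(tile, dtype=float)
    return px[..., 0] * 0.2125 + px[..., 1] * 0.7154 + px[..., 2] * 0.0721


def wavelet_texture(tile: np.ndarray, instance: NucleusInstance,
                    wavelet: str = "haar", scope: str = "nucleus"
                    ) -> tuple[float, float]:
    """(cD_average, cD_var) from a single-level 2-D DWT.

    ``scope="nucleus"`` (default) transforms the grayscale bounding-box patch
    of the instance with non-nucleus pixels zeroed; ``scope="tile"`` transforms
    the whole grayscale tile.  The transform uses periodised boundary handling,
    which for even-sized patches equals the plain decimated two-step filter
    bank (rows then columns) with the Haar filters g = (1, 1)/sqrt(2),
    h = (1, -1)/sqrt(2).
    """
    gray = _grayscale(tile)
    if scope == "nucleus":
        mask, (r0, c0) = instance.silhouette()
        h, w = mask.shape
        patch = gray[r0:r0 + h, c0:c0 + w] * mask
    elif scope == "tile":
        patch = gray
    else:
        raise ValueError(f"unknown scope {scope!r}")
    min_side = 2 * (len(pywt.Wavelet(wavelet).dec_lo) // 2)
    if min(patch.shape) < max(2, min_side):
        raise ValueError(
            f"patch {patch.shape} smaller than the minimum side {max(2, min_side)}"
            f" for wavelet {wavelet!r}")
    _, (_, _, cd) = pywt.dwt2(patch, wavelet, mode="periodization")
    return float(cd.mean()), float(cd.var())


def extract_features(tile: np.ndarray, instances: list[NucleusInstance],
                     patient_id: str = "", tile_id: str = "",
                     wavelet: str = "haar", wavelet_scope: str = "nucleus",
                     ) -> pd.DataFrame:
    """One feature row per (already quality-filtered) nucleus.

    Returns a DataFrame with identifier columns (patient_id, tile_id, label)
    followed by exactly the 20 ``FEATURE_COLUMNS``.  Per-nucleus failures are
    logged and the nucleus dropped, never imputed.
    """
    import logging

    rows = []
    for inst in instances:
        try:
            r_avg, g_avg, b_avg, r_var, g_var, b_var = color_stats(tile, inst)
            area, perim, circ, comp, ecc = shape_descriptors(inst)
            mask, _ = inst.silhouette()
            hu = hu_moments(mask)
            cd_avg, cd_var = wavelet_texture(tile, inst, wavelet=wavelet,
                                             scope=wavelet_scope)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logging.getLogger(__name__).warning(
                "dropping nucleus %s/%s label %d: %s",
                patient_id, tile_id, inst.label, exc)
            continue
        rows.append({
            "patient_id": patient_id, "tile_id": tile_id, "label": inst.label,
            "R_average": r_avg, "G_average": g_avg, "B_average": b_avg,
            "R_var": r_var, "G_var": g_var, "B_var": b_var,
            "Area": area, "Perimeter": perim, "Circularity": circ,
            "Compactness": comp, "Eccentric": ecc,
            **{f"Hu{i}": hu[i] for i in range(7)},
            "cD_average": cd_avg, "cD_var": cd_var,
        })
    columns = ["patient_id", "tile_id", "label", *FEATURE_COLUMNS]
    return pd.DataFrame(rows, columns=columns)
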