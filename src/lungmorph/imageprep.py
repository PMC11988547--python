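"""Tiling, blank-tile exclusion and histogram-matching stain normalisation.

Whole-slide scans are cut into fixed-size RGB tiles on a row-major grid
(0-based indices, top-left origin); edge remainders smaller than the tile size
are dropped so every tile has the stated uniform size.  Tiles whose content is
almost entirely unstained near-white background are excluded.  Colour
variation between slides is removed by per-channel histogram matching to a
reference image chosen for optimal staining.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.exposure import match_histograms

__all__ = [
    "Tile",
    "tile_image",
    "is_blank",
    "histogram_match",
    "read_image",
]

#: default tile edge, px
DEFAULT_TILE_SIZE = 1024
#: a pixel is "near-white" when all channels are >= this 8-bit cutoff
WHITE_CUTOFF = 220
#: a tile is blank when more than this fraction of pixels are near-white
BLANK_FRACTION = 0.9


@dataclass
class Tile:
    """A fixed-size RGB tile with its grid position on the source image."""

    pixels: np.ndarray  # H×W×3 uint8
    slide_id: str = ""
    grid_x: int = 0
    grid_y: int = 0
    level: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("tile pixels must be H×W×3")


def read_image(path: str | Path) -> np.ndarray:
    """Read a plain PNG/TIFF image as an H×W×3 uint8 array."""
    import imageio.v3 as iio

    p = Path(path)
    if not p.exists():
        raise IOError(f"cannot read image: {p}")
    img = np.asarray(iio.imread(p))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img[..., :3].astype(np.uint8)


def tile_image(source: np.ndarray | str | Path, tile_size: int = DEFAULT_TILE_SIZE,
               level: int = 0, slide_id: str | None = None) -> list[Tile]:
    """Cut ``source`` into non-overlapping ``tile_size``-square tiles.

    Tiles are emitted in row-major order of their 0-based grid indices
    ``(grid_y, grid_x)``; edge remainders are dropped, never padded.  ``level``
    is carried through for pyramid sources; plain images have a single level 0.
    """
    if isinstance(source, (str, Path)):
        if slide_id is None:
            slide_id = Path(source).stem
        source = read_image(source)
    if level != 0:
        raise IndexError(f"plain images expose only level 0, got level {level}")
    img = np.asarray(source)
    if img.ndim != 3:
        raise ValueError("source must be an H×W×3 image")
    h, w = img.shape[:2]
    tiles = []
    for gy in range(h // tile_size):
        for gx in range(w // tile_size):
            block = img[gy * tile_size:(gy + 1) * tile_size,
                        gx * tile_size:(gx + 1) * tile_size]
            tiles.append(Tile(pixels=block, slide_id=slide_id or "",
                              grid_x=gx, grid_y=gy, level=level))
    return tiles


def is_blank(tile: Tile | np.ndarray, white_cutoff: int = WHITE_CUTOFF,
             blank_fraction: float = BLANK_FRACTION) -> bool:
    """True iff the fraction of near-white pixels exceeds ``blank_fraction``.

    Near-white means every channel at or above ``white_cutoff``; the rule
    targets unstained white background, so an all-black tile is not blank.
    """
    px = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    near_white = np.all(px >= white_cutoff, axis=-1)
    return bool(near_white.mean() > blank_fraction)


def histogram_match(tile: Tile | np.ndarray, ref: Tile | np.ndarray) -> Tile | np.ndarray:
    """Match each RGB channel of ``tile`` to the reference's channel histogram.

    Output values are the reference-channel quantile function applied to the
    tile-channel empirical CDF; dtype and shape equal the input.  Matching a
    tile to itself is the identity up to 8-bit quantisation.
    """
    px = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    ref_px = ref.pixels if isinstance(ref, Tile) else np.asarray(ref)
    if px.size == 0 or ref_px.size == 0:
        raise ValueError("histogram matching requires nonempty images")
    matched = match_histograms(px, ref_px, channel_axis=-1)
    matched = np.asarray(matched).astype(px.dtype)
    if isinstance(tile, Tile):
        return Tile(pixels=matched, slide_id=tile.slide_id,
                    grid_x=tile.grid_x, grid_y=tile.grid_y, level=tile.level)
    return matched
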