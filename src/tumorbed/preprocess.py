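"""HSV tissue masking and foreground-filtered tiling.

Glass background carries no nuclei and is irrelevant for tumor detection, so
slides are thresholded in HSV space before tiling.  The default bounds —
0.5 < hue < 0.65, saturation > 0.1, 0.5 < value < 0.9, all strict — pick out
hematoxylin-stained tissue against bright background.  Tiling then walks a
regular stride grid and keeps only patches whose windows contain at least
``min_fg`` (default 25%, inclusive) foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv


@dataclass(frozen=True)
class HsvBounds:
    hue_lo: float = 0.5
    hue_hi: float = 0.65
    sat_lo: float = 0.1
    val_lo: float = 0.5
    val_hi: float = 0.9

    def __post_init__(self):
        if not (0 <= self.hue_lo < self.hue_hi <= 1):
            raise ValueError("require 0 <= hue_lo < hue_hi <= 1")
        if not (0 <= self.val_lo < self.val_hi <= 1):
            raise ValueError("require 0 <= val_lo < val_hi <= 1")
        if not (0 <= self.sat_lo <= 1):
            raise ValueError("sat_lo must be in [0, 1]")


def hsv_foreground_mask(image: np.ndarray, bounds: HsvBounds | None = None) -> np.ndarray:
    """Boolean foreground mask of an RGB image.

    A pixel is foreground iff hue_lo < h < hue_hi and s > sat_lo and
    val_lo < v < val_hi (all inequalities strict).  ``image`` may be uint8
    or float RGB, or an already-converted H×W×3 HSV array is accepted via
    :func:`hsv_mask_from_hsv`.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H×W×3 RGB image")
    hsv = rgb2hsv(image)
    return hsv_mask_from_hsv(hsv, bounds)


def hsv_mask_from_hsv(hsv: np.ndarray, bounds: HsvBounds | None = None) -> np.ndarray:
    b = bounds or HsvBounds()
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    return ((h > b.hue_lo) & (h < b.hue_hi)
            & (s > b.sat_lo)
            & (v > b.val_lo) & (v < b.val_hi))


@dataclass
class TileGrid:
    """Half-open patch windows [x, x+patch) × [y, y+patch) over a slide.

    ``tiles`` has one row per grid position with columns
    x, y, foreground_ratio, kept.
    """

    patch_px: int
    stride_px: int
    shape: tuple[int, int]  # (H, W)
    min_fg: float
    tiles: pd.DataFrame = field(repr=False)

    @property
    def kept(self) -> pd.DataFrame:
        return self.tiles[self.tiles["kept"]]

    def to_manifest(self, slide_id: str) -> pd.DataFrame:
        df = self.tiles.copy()
        df.insert(0, "slide_id", slide_id)
        df["patch_px"] = self.patch_px
        df["stride_px"] = self.stride_px
        return df


def _window_sums(mask: np.ndarray, patch: int, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(mask.astype(np.int64), axis=0), axis=1)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return (ii[yy + patch, xx + patch] - ii[yy, xx + patch]
            - ii[yy + patch, xx] + ii[yy, xx])


def tile_slide(shape: tuple[int, int], patch_px: int, stride_px: int,
               mask: np.ndarray, min_fg: float = 0.25) -> TileGrid:
    """Tile a slide of ``shape`` (H, W) and flag foreground patches.

    Windows start at multiples of ``stride_px`` and must lie fully inside the
    slide (overhanging edge tiles are dropped, no padding).  A tile is kept
    iff its foreground ratio is >= ``min_fg`` (inclusive).
    """
    h, w = shape
    if stride_px <= 0:
        raise ValueError("stride_px must be positive")
    if stride_px > patch_px:
        raise ValueError("stride_px must not exceed patch_px")
    if patch_px > min(h, w):
        raise ValueError("patch_px larger than slide")
    mask = np.asarray(mask)
    if mask.shape != (h, w):
        raise ValueError("mask shape does not match slide shape")

    xs = np.arange(0, w - patch_px + 1, stride_px)
    ys = np.arange(0, h - patch_px + 1, stride_px)
    sums = _window_sums(mask != 0, patch_px, xs, ys)
    ratio = sums / float(patch_px * patch_px)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    tiles = pd.DataFrame({
        "x": xx.ravel(), "y": yy.ravel(),
        "foreground_ratio": ratio.ravel(),
        "kept": ratio.ravel() >= min_fg,
    })
    return TileGrid(patch_px=patch_px, stride_px=stride_px, shape=(h, w),
                    min_fg=min_fg, tiles=tiles)
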