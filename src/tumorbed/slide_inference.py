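"""Sliding-window inference with per-pixel probability voting.

A binary patch classifier is run over every kept foreground tile of a slide.
When the stride is smaller than the patch size, each pixel is covered by
several windows — (patch/stride)² of them in the interior — and the per-
window probabilities are averaged into a per-pixel heatmap, which both
smooths the prediction and injects context from neighboring windows.
Thresholding the heatmap yields a tumor mask; the slide is called
tumor-positive as soon as a single tile's own probability crosses the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

from .preprocess import HsvBounds, TileGrid, hsv_foreground_mask, tile_slide
from .synthetic_slide import LABEL_FREE, LABEL_POSITIVE
from .training_support import tta_predict


@dataclass
class HeatMap:
    """Accumulated probability sum and vote count per pixel."""

    prob_sum: np.ndarray    # H×W float64
    vote_count: np.ndarray  # H×W int32

    @property
    def mean(self) -> np.ndarray:
        """Mean probability where votes exist, 0 elsewhere."""
        out = np.zeros_like(self.prob_sum)
        np.divide(self.prob_sum, self.vote_count, out=out,
                  where=self.vote_count > 0)
        return out


@dataclass
class SlidePrediction:
    heatmap: HeatMap
    tumor_mask: np.ndarray
    tile_probs: pd.DataFrame       # kept tiles with their own probabilities
    positive_tiles: pd.DataFrame   # tiles with prob >= threshold
    slide_label: str
    threshold: float
    grid: TileGrid


def votes_per_pixel(patch_px: int, stride_px: int) -> int:
    """Windows covering an interior pixel when stride divides patch:
    (patch/stride)².  E.g. patch 512 at stride 256 → 4, at stride 16 → 1024."""
    if stride_px <= 0:
        raise ValueError("stride must be positive")
    if stride_px > patch_px:
        raise ValueError("stride must not exceed patch size")
    if patch_px % stride_px != 0:
        raise ValueError("stride must divide patch size for this helper; "
                         "the heatmap accumulator handles the general case")
    return (patch_px // stride_px) ** 2


def _classify_tiles(image: np.ndarray, kept: pd.DataFrame, patch_px: int,
                    classifier, tta_n: int, rng, input_px: int,
                    batch_size: int) -> np.ndarray:
    if hasattr(classifier, "predict_windows"):
        return np.asarray(classifier.predict_windows(
            kept["x"].to_numpy(), kept["y"].to_numpy(), patch_px), dtype=float)
    xs = kept["x"].to_numpy()
    ys = kept["y"].to_numpy()
    probs = np.empty(len(kept))
    if tta_n > 1:
        for i, (x, y) in enumerate(zip(xs, ys)):
            probs[i] = tta_predict(classifier, image[y:y + patch_px, x:x + patch_px],
                                   tta_n=tta_n, rng=rng)
        return probs
    for start in range(0, len(kept), batch_size):
        batch = []
        for x, y in zip(xs[start:start + batch_size], ys[start:start + batch_size]):
            win = image[y:y + patch_px, x:x + patch_px]
            win = win.astype(np.float64) / 255.0 if win.dtype == np.uint8 else win
            if win.shape[:2] != (input_px, input_px):
                win = resize(win, (input_px, input_px, 3), anti_aliasing=True)
            batch.append(win)
        probs[start:start + len(batch)] = np.asarray(classifier(np.stack(batch)),
                                                     dtype=float)
    return probs


def infer_heatmap(image: np.ndarray, grid: TileGrid, classifier, *,
                  tta_n: int = 1, rng: np.random.Generator | None = None,
                  input_px: int = 224,
                  batch_size: int = 64) -> tuple[HeatMap, pd.DataFrame]:
    """Classify every kept tile and accumulate votes into a heatmap.

    Returns the heatmap and the kept-tile table with a ``prob`` column.
    Skipped (background) tiles contribute nothing: their pixels keep zero
    votes.  Classifiers exposing ``predict_windows`` (e.g. the ground-truth
    oracle) are called with coordinates; plain classifiers receive windows
    resized to ``input_px``.
    """
    h, w = grid.shape
    kept = grid.kept.reset_index(drop=True)
    prob_sum = np.zeros((h, w), dtype=np.float64)
    vote_count = np.zeros((h, w), dtype=np.int32)
    probs = _classify_tiles(image, kept, grid.patch_px, classifier,
                            tta_n, rng or np.random.default_rng(0),
                            input_px, batch_size)
    if len(probs) and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("classifier produced probabilities outside [0, 1]")
    p = grid.patch_px
    for (x, y, prob) in zip(kept["x"].to_numpy(), kept["y"].to_numpy(), probs):
        prob_sum[y:y + p, x:x + p] += prob
        vote_count[y:y + p, x:x + p] += 1
    return (HeatMap(prob_sum=prob_sum, vote_count=vote_count),
            kept.assign(prob=probs))


def threshold_mask(heatmap: HeatMap, tile_probs: pd.DataFrame,
                   threshold: float = 0.5) -> tuple[np.ndarray, pd.DataFrame]:
    """Pixel mask (mean >= threshold where votes exist, inclusive) and the
    list of positive tiles (a tile is positive by its own probability)."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    mask = (heatmap.vote_count > 0) & (heatmap.mean >= threshold)
    positive = tile_probs[tile_probs["prob"] >= threshold]
    return mask, positive


def slide_label(positive_tiles) -> str:
    """Tumor-positive iff at least one positive tile exists."""
    n = len(positive_tiles.positive_tiles if isinstance(positive_tiles, SlidePrediction)
            else positive_tiles)
    return LABEL_POSITIVE if n > 0 else LABEL_FREE


def predict_slide(image: np.ndarray, classifier, *, patch_px: int,
                  stride_px: int, min_fg: float = 0.25,
                  bounds: HsvBounds | None = None, threshold: float = 0.5,
                  tta_n: int = 1,
                  rng: np.random.Generator | None = None) -> SlidePrediction:
    """Full single-slide pipeline: tissue mask → tile grid → vote heatmap →
    threshold mask → slide label."""
    fg = hsv_foreground_mask(image, bounds)
    grid = tile_slide(fg.shape, patch_px, stride_px, fg, min_fg)
    heatmap, tile_probs = infer_heatmap(image, grid, classifier,
                                        tta_n=tta_n, rng=rng)
    mask, positive = threshold_mask(heatmap, tile_probs, threshold)
    return SlidePrediction(heatmap=heatmap, tumor_mask=mask,
                           tile_probs=tile_probs, positive_tiles=positive,
                           slide_label=slide_label(positive),
                           threshold=threshold, grid=grid)
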