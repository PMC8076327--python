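"""Class-imbalance policies, augmentation pipeline, and the patch-classifier
contract.

After negative mining the training set is heavily skewed toward negatives
(roughly 85% in the reference setting).  Two families of remedies are
provided: per-class loss weights (proportional, inverse-proportional, or
equal) and minority oversampling, where each class is repeated
round(N_max/N_c) times per epoch so that per-class epoch shares roughly
equalize.

The augmentation pipeline mirrors the standard patch recipe: a 512-px source
patch is randomly cropped to 448, optionally affine-transformed (scale ±10%,
shear up to ±60° per axis) and color-jittered (brightness/contrast/
saturation/hue each perturbed by up to 5%), then resized to the 224-px
classifier input.  Test-time augmentation averages classifier probabilities
over randomly cropped/flipped/rotated variants.

A ``PatchClassifier`` is any callable mapping a batch of H×W×3 patches to
probabilities in [0, 1]; two toy classifiers (a ground-truth oracle and an
HSV color-fraction scorer) exercise the contract without a trained network.
Training loops themselves are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, runtime_checkable

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import AffineTransform, resize, warp


# ---------------------------------------------------------------------------
# Imbalance policies

def class_weights(counts: Mapping[str, int], mode: str,
                  normalize: bool = False) -> dict[str, float]:
    """Per-class loss weights.

    proportional: w_c = K·N_c/N  (classes weighted by their share)
    inverse:      w_c = N/(K·N_c)
    equal:        w_c = 1
    With ``normalize=True`` weights are divided by their mean so the mean
    normalized weight is exactly 1 in every mode.
    """
    if len(counts) < 2:
        raise ValueError("need at least two classes")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be positive")
    k = len(counts)
    if mode == "equal":
        w = {c: 1.0 for c in counts}
    elif mode == "proportional":
        w = {c: k * n / total for c, n in counts.items()}
    elif mode == "inverse":
        if any(n == 0 for n in counts.values()):
            raise ValueError("zero count in a weighted class")
        w = {c: total / (k * n) for c, n in counts.items()}
    else:
        raise ValueError(f"unknown weight mode: {mode!r}")
    if normalize:
        mean = sum(w.values()) / k
        w = {c: v / mean for c, v in w.items()}
    return w


def oversampling_plan(counts: Mapping[str, int], multiplier: int = 1) -> dict[str, int]:
    """Integer repetitions per class: r_c = max(1, round(N_max/N_c)) · m.

    The majority class gets r = 1 (at m = 1); minority classes are repeated
    until their epoch share approaches the majority's.
    """
    if not counts:
        raise ValueError("empty counts")
    if any(n <= 0 for n in counts.values()):
        raise ValueError("all class counts must be positive")
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    n_max = max(counts.values())
    return {c: multiplier * max(1, round(n_max / n)) for c, n in counts.items()}


# ---------------------------------------------------------------------------
# Augmentation

@dataclass(frozen=True)
class AugmentationSpec:
    """Knobs for the crop → affine → color-jitter → resize pipeline.

    Zeroing every knob (and setting crop_px to the source size) makes the
    pipeline the identity up to the final resize.
    """

    source_px: int = 512
    crop_px: int = 448
    out_px: int = 224
    color_jitter_frac: float = 0.05
    scale_frac: float = 0.10
    shear_deg: float = 60.0
    tta_n: int = 2

    def __post_init__(self):
        if self.crop_px > self.source_px:
            raise ValueError("crop_px must not exceed source_px")
        if not (0 <= self.color_jitter_frac <= 1):
            raise ValueError("color_jitter_frac must be in [0, 1]")
        if self.scale_frac < 0 or self.shear_deg < 0:
            raise ValueError("augmentation magnitudes must be nonnegative")
        if self.tta_n < 1:
            raise ValueError("tta_n must be >= 1")


def _to_float(patch: np.ndarray) -> np.ndarray:
    patch = np.asarray(patch)
    if patch.dtype == np.uint8:
        return patch.astype(np.float64) / 255.0
    return patch.astype(np.float64)


def color_jitter(img: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Perturb brightness, contrast, saturation and hue, each by at most
    ``frac`` of its original value (hue: additive shift of up to ``frac`` of
    the hue circle)."""
    if frac == 0:
        return img
    out = img * rng.uniform(1 - frac, 1 + frac)                      # brightness
    mean = out.mean()
    out = mean + (out - mean) * rng.uniform(1 - frac, 1 + frac)      # contrast
    out = np.clip(out, 0, 1)
    hsv = rgb2hsv(out)
    hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(1 - frac, 1 + frac), 0, 1)
    hsv[..., 0] = np.mod(hsv[..., 0] + rng.uniform(-frac, frac), 1.0)
    return hsv2rgb(hsv)


def _random_affine(img: np.ndarray, spec: AugmentationSpec,
                   rng: np.random.Generator) -> np.ndarray:
    scale = rng.uniform(1 - spec.scale_frac, 1 + spec.scale_frac)
    shear_x = np.deg2rad(rng.uniform(-spec.shear_deg, spec.shear_deg))
    shear_y = np.deg2rad(rng.uniform(-spec.shear_deg, spec.shear_deg))
    h, w = img.shape[:2]
    center = np.array([w / 2.0, h / 2.0])
    tf = (AffineTransform(translation=-center)
          + AffineTransform(scale=(scale, scale), shear=(shear_x, shear_y))
          + AffineTransform(translation=center))
    return warp(img, tf.inverse, mode="reflect", order=1)


def augment(patch: np.ndarray, spec: AugmentationSpec,
            rng: np.random.Generator) -> np.ndarray:
    """Apply the pipeline crop → affine → color jitter → resize.

    Returns a float image in [0, 1] of shape (out_px, out_px, 3).  With all
    knobs zeroed and crop_px == source size, the output is the input resized
    to out_px (exactly the input when the sizes already match).
    """
    img = _to_float(patch)
    h, w = img.shape[:2]
    if spec.crop_px > min(h, w):
        raise ValueError("patch smaller than crop size")
    if spec.crop_px < h or spec.crop_px < w:
        top = int(rng.integers(0, h - spec.crop_px + 1))
        left = int(rng.integers(0, w - spec.crop_px + 1))
        img = img[top:top + spec.crop_px, left:left + spec.crop_px]
    if spec.scale_frac > 0 or spec.shear_deg > 0:
        img = _random_affine(img, spec, rng)
    if spec.color_jitter_frac > 0:
        img = color_jitter(img, spec.color_jitter_frac, rng)
    if img.shape[:2] != (spec.out_px, spec.out_px):
        img = resize(img, (spec.out_px, spec.out_px, 3), anti_aliasing=True)
    return np.clip(img, 0, 1)


def _center_crop(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape[:2]
    top = (h - size) // 2
    left = (w - size) // 2
    return img[top:top + size, left:left + size]


# ---------------------------------------------------------------------------
# Classifier contract and TTA

@runtime_checkable
class PatchClassifier(Protocol):
    """Callable mapping a (B, H, W, 3) batch to (B,) probabilities in [0, 1]."""

    def __call__(self, patches: np.ndarray) -> np.ndarray: ...


def tta_predict(classifier, patch: np.ndarray, tta_n: int = 2,
                rng: np.random.Generator | None = None,
                spec: AugmentationSpec | None = None) -> float:
    """Mean classifier probability over test-time augmented variants.

    Variant 0 is always the deterministic center crop; further variants draw
    a random crop plus a random flip and a random 90° rotation.  tta_n = 1 is
    therefore deterministic.
    """
    if tta_n < 1:
        raise ValueError("tta_n must be >= 1")
    img = _to_float(patch)
    side = min(img.shape[:2])
    if spec is None:
        crop = min(448, side)
        spec = AugmentationSpec(source_px=side, crop_px=crop, out_px=224,
                                color_jitter_frac=0.0, scale_frac=0.0,
                                shear_deg=0.0, tta_n=tta_n)
    rng = rng or np.random.default_rng(0)

    def finish(v):
        if v.shape[:2] != (spec.out_px, spec.out_px):
            v = resize(v, (spec.out_px, spec.out_px, 3), anti_aliasing=True)
        return v

    variants = [finish(_center_crop(img, spec.crop_px))]
    for _ in range(tta_n - 1):
        v = img
        if spec.crop_px < min(v.shape[:2]):
            top = int(rng.integers(0, v.shape[0] - spec.crop_px + 1))
            left = int(rng.integers(0, v.shape[1] - spec.crop_px + 1))
            v = v[top:top + spec.crop_px, left:left + spec.crop_px]
        if rng.integers(2):
            v = v[:, ::-1]
        v = np.rot90(v, k=int(rng.integers(4)))
        variants.append(finish(v))
    probs = np.asarray(classifier(np.stack(variants)), dtype=float)
    return float(probs.mean())


# ---------------------------------------------------------------------------
# Toy classifiers

class ColorFracClassifier:
    """Probability = fraction of pixels inside an HSV 'tumor-color' box.

    The default box matches the synthetic generator's tumor paint and
    excludes benign tissue; it is rotation- and flip-invariant by
    construction.
    """

    def __init__(self, hue=(0.575, 0.66), sat_lo: float = 0.40, val=(0.45, 0.80)):
        self.hue = hue
        self.sat_lo = sat_lo
        self.val = val

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches)
        if patches.ndim == 3:
            patches = patches[None]
        out = np.empty(len(patches))
        for i, p in enumerate(patches):
            hsv = rgb2hsv(_to_float(p))
            inside = ((hsv[..., 0] > self.hue[0]) & (hsv[..., 0] < self.hue[1])
                      & (hsv[..., 1] > self.sat_lo)
                      & (hsv[..., 2] > self.val[0]) & (hsv[..., 2] < self.val[1]))
            out[i] = inside.mean()
        return out


class OracleClassifier:
    """Ground-truth oracle: 1 if the patch window intersects the tumor mask.

    Needs window coordinates, so it exposes ``predict_windows`` (used by the
    slide-inference driver) instead of the pixel-only call path.
    """

    def __init__(self, tumor_mask: np.ndarray):
        if tumor_mask is None:
            raise ValueError("oracle classifier requires a ground-truth mask")
        mask = np.asarray(tumor_mask) != 0
        ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
        ii[1:, 1:] = np.cumsum(np.cumsum(mask.astype(np.int64), 0), 1)
        self._ii = ii
        self.shape = mask.shape

    def predict_windows(self, xs, ys, patch_px: int) -> np.ndarray:
        xs = np.asarray(xs, dtype=int)
        ys = np.asarray(ys, dtype=int)
        ii = self._ii
        sums = (ii[ys + patch_px, xs + patch_px] - ii[ys, xs + patch_px]
                - ii[ys + patch_px, xs] + ii[ys, xs])
        return (sums > 0).astype(float)

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        raise TypeError("the oracle classifier needs window coordinates; "
                        "use predict_windows via the slide-inference driver")


def toy_classifier(mode: str, **kwargs):
    """Factory for the built-in toy classifiers: 'oracle' (requires
    tumor_mask=...) or 'colorfrac'."""
    if mode == "oracle":
        return OracleClassifier(kwargs.get("tumor_mask"))
    if mode == "colorfrac":
        return ColorFracClassifier(**kwargs)
    raise ValueError(f"unknown toy classifier mode: {mode!r}")
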