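"""Reduced-scale synthetic whole-slide images for pipeline testing.

Real post-treatment breast resection slides are gigapixel scans: mostly bright
glass background, irregular tissue regions, and — somewhere inside the tissue
— a tumor bed whose extent is the quantity of clinical interest.  Slides also
carry artifacts that trip up naive classifiers: ink or staining residue,
locally out-of-focus regions, creases, and fields of red blood cells.

This module emulates those slides at desk scale (single-resolution rasters,
a few megapixels).  Tissue and tumor are painted with hue/saturation/value
statistics that fall inside the HSV foreground bounds used by
:mod:`tumorbed.preprocess`, background and artifacts fall outside them, and
every slide ships with an exact ground-truth tumor mask, polygon annotations
and a slide-level label.  Visual realism is a non-goal; what matters is that
classes are separable for the toy classifiers and that the geometry of the
ground truth is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import hsv2rgb

from .geometry import ccw_vertices, polygon_in_bounds, random_convex_polygon, rasterize_polygon

# HSV painting statistics.  Tissue and tumor sit strictly inside the default
# foreground bounds (0.5 < h < 0.65, s > 0.1, 0.5 < v < 0.9); tumor is pushed
# to the high-hue / high-saturation corner so a simple color-box classifier
# can separate it from benign tissue.
TISSUE_HSV = (0.530, 0.25, 0.80)
TUMOR_HSV = (0.620, 0.55, 0.62)
DEFAULT_BACKGROUND_HSV = (0.0, 0.02, 0.97)
DEFAULT_ARTIFACTS: Mapping[str, int] = {"ink": 2, "blur": 1, "rbc": 3, "crease": 1}

LABEL_POSITIVE = "tumor-positive"
LABEL_FREE = "tumor-free"


@dataclass(frozen=True)
class SlideSpec:
    """Everything needed to deterministically generate one synthetic slide."""

    width_px: int
    height_px: int
    mpp: float = 1.0  # microns per pixel
    tumor_polygons: tuple = ()
    artifact_counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_ARTIFACTS))
    background_hsv: tuple[float, float, float] = DEFAULT_BACKGROUND_HSV
    seed: int = 0
    tissue_polygons: tuple | None = None  # None → auto blob containing the tumors

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        for poly in self.tumor_polygons:
            if not polygon_in_bounds(poly, self.width_px, self.height_px):
                raise ValueError(
                    "tumor polygon extends outside the %dx%d slide bounds"
                    % (self.width_px, self.height_px))
        for kind in self.artifact_counts:
            if kind not in ("ink", "blur", "rbc", "crease"):
                raise ValueError(f"unknown artifact kind: {kind!r}")


@dataclass
class SyntheticSlide:
    image: np.ndarray        # H×W×3 uint8 RGB
    tumor_mask: np.ndarray   # H×W bool
    slide_label: str
    spec: SlideSpec


def _noisy(rng, base, sigma, lo, hi, shape):
    return np.clip(base + rng.normal(0.0, sigma, shape), lo, hi)


def _auto_tissue(rng, spec: SlideSpec) -> np.ndarray:
    """A convex blob guaranteed to contain every tumor polygon."""
    from scipy.spatial import ConvexHull

    w, h = spec.width_px, spec.height_px
    cx = w / 2 + rng.uniform(-0.04, 0.04) * w
    cy = h / 2 + rng.uniform(-0.04, 0.04) * h
    ang = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    rad_x = w * rng.uniform(0.36, 0.44)
    rad_y = h * rng.uniform(0.36, 0.44)
    pts = np.column_stack([cx + rad_x * np.cos(ang), cy + rad_y * np.sin(ang)])
    for poly in spec.tumor_polygons:
        pts = np.vstack([pts, np.asarray(poly, dtype=float)])
    pts[:, 0] = np.clip(pts[:, 0], 0, w - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, h - 1)
    hull = ConvexHull(pts)
    return ccw_vertices(pts[hull.vertices])


def _paint(hsv, region, rng, base, sigmas, bounds):
    n = int(region.sum())
    if n == 0:
        return
    for ch in range(3):
        hsv[..., ch][region] = _noisy(rng, base[ch], sigmas[ch], *bounds[ch], n)


def _draw_disk(channel_region, cy, cx, radius, shape):
    h, w = shape
    r0, r1 = max(0, int(cy - radius)), min(h, int(cy + radius) + 1)
    c0, c1 = max(0, int(cx - radius)), min(w, int(cx + radius) + 1)
    if r1 <= r0 or c1 <= c0:
        return
    rr, cc = np.ogrid[r0:r1, c0:c1]
    channel_region[r0:r1, c0:c1] |= (rr - cy) ** 2 + (cc - cx) ** 2 <= radius ** 2


def _apply_artifacts(hsv, rng, spec: SlideSpec) -> None:
    h, w = hsv.shape[:2]
    scale = min(h, w)
    counts = spec.artifact_counts
    for _ in range(int(counts.get("ink", 0))):
        region = np.zeros((h, w), dtype=bool)
        _draw_disk(region, rng.uniform(0, h), rng.uniform(0, w),
                   rng.uniform(0.02, 0.05) * scale, (h, w))
        _paint(hsv, region, rng, (0.75, 0.60, 0.15),
               (0.01, 0.03, 0.02),
               ((0.7, 0.8), (0.5, 0.7), (0.05, 0.25)))
    for _ in range(int(counts.get("rbc", 0))):
        region = np.zeros((h, w), dtype=bool)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        for _ in range(rng.integers(8, 20)):
            _draw_disk(region, cy + rng.normal(0, 0.02 * scale),
                       cx + rng.normal(0, 0.02 * scale),
                       rng.uniform(0.002, 0.005) * scale, (h, w))
        _paint(hsv, region, rng, (0.985, 0.75, 0.75),
               (0.004, 0.04, 0.04),
               ((0.97, 0.999), (0.6, 0.9), (0.6, 0.9)))
    for _ in range(int(counts.get("crease", 0))):
        region = np.zeros((h, w), dtype=bool)
        y, x = rng.uniform(0, h), rng.uniform(0, w)
        direction = rng.uniform(0, 2 * np.pi)
        for _ in range(int(0.5 * scale)):
            direction += rng.normal(0, 0.2)
            y = np.clip(y + 2 * np.sin(direction), 0, h - 1)
            x = np.clip(x + 2 * np.cos(direction), 0, w - 1)
            _draw_disk(region, y, x, rng.uniform(1.0, 2.5), (h, w))
        _paint(hsv, region, rng, (0.6, 0.2, 0.30),
               (0.02, 0.03, 0.03),
               ((0.5, 0.7), (0.1, 0.3), (0.2, 0.42)))
    for _ in range(int(counts.get("blur", 0))):
        from scipy.ndimage import uniform_filter

        side = int(rng.uniform(0.05, 0.12) * scale)
        r0 = int(rng.uniform(0, max(1, h - side)))
        c0 = int(rng.uniform(0, max(1, w - side)))
        patch = hsv[r0:r0 + side, c0:c0 + side]
        hsv[r0:r0 + side, c0:c0 + side] = uniform_filter(patch, size=(9, 9, 1), mode="nearest")


def generate_slide(spec: SlideSpec) -> SyntheticSlide:
    """Generate a synthetic slide with exact ground truth.

    Deterministic: the same spec (including seed) yields a byte-identical
    image.  Artifacts never overwrite tumor pixels, so the tumor mask stays
    exactly the rasterization of ``spec.tumor_polygons``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    hsv = np.empty((h, w, 3), dtype=float)

    bh, bs, bv = spec.background_hsv
    hsv[..., 0] = _noisy(rng, bh, 0.003, 0.0, 1.0, (h, w))
    hsv[..., 1] = _noisy(rng, bs, 0.005, 0.0, 0.08, (h, w))
    hsv[..., 2] = _noisy(rng, bv, 0.005, 0.92, 1.0, (h, w))

    tissue_polys = spec.tissue_polygons
    if tissue_polys is None:
        tissue_polys = (_auto_tissue(rng, spec),)
    tissue_mask = np.zeros((h, w), dtype=bool)
    for poly in tissue_polys:
        tissue_mask |= rasterize_polygon(poly, (h, w))
    _paint(hsv, tissue_mask, rng, TISSUE_HSV,
           (0.004, 0.03, 0.03),
           ((0.51, 0.56), (0.15, 0.35), (0.55, 0.88)))

    tumor_mask = np.zeros((h, w), dtype=bool)
    for poly in spec.tumor_polygons:
        tumor_mask |= rasterize_polygon(poly, (h, w))
    _paint(hsv, tumor_mask, rng, TUMOR_HSV,
           (0.004, 0.03, 0.03),
           ((0.60, 0.645), (0.45, 0.65), (0.52, 0.72)))

    # Artifacts live outside the tumor bed: draw them anywhere, then restore
    # the tumor pixels so the ground-truth mask remains exact.
    saved = hsv[tumor_mask].copy()
    _apply_artifacts(hsv, rng, spec)
    hsv[tumor_mask] = saved

    image = (hsv2rgb(hsv) * 255.0).round().astype(np.uint8)
    label = LABEL_POSITIVE if tumor_mask.any() else LABEL_FREE
    return SyntheticSlide(image=image, tumor_mask=tumor_mask, slide_label=label, spec=spec)


def random_cohort_specs(n_slides: int, width_px: int, height_px: int, *,
                        tumor_fraction: float = 0.7, mpp: float = 1.0,
                        tumor_radius_frac: tuple[float, float] = (0.12, 0.22),
                        seed: int = 0) -> list[SlideSpec]:
    """Specs for a cohort where ``tumor_fraction`` of slides carry one
    convex tumor polygon inside the tissue blob; the rest are tumor-free."""
    rng = np.random.default_rng(seed)
    n_pos = int(round(tumor_fraction * n_slides))
    specs = []
    for i in range(n_slides):
        slide_seed = int(rng.integers(0, 2**31 - 1))
        if i < n_pos:
            sub = np.random.default_rng(slide_seed + 1)
            cx = width_px * sub.uniform(0.42, 0.58)
            cy = height_px * sub.uniform(0.42, 0.58)
            radius = min(width_px, height_px) * sub.uniform(*tumor_radius_frac)
            # rounded blobs: post-treatment tumor beds are compact regions
            poly = random_convex_polygon(sub, (cx, cy), radius, n_points=16,
                                         r_range=(0.6, 1.0))
            polys: tuple = (poly,)
        else:
            polys = ()
        specs.append(SlideSpec(width_px=width_px, height_px=height_px, mpp=mpp,
                               tumor_polygons=polys, seed=slide_seed))
    return specs


# ---------------------------------------------------------------------------
# Feature clouds: stand-ins for pooled CNN patch descriptors.

@dataclass(frozen=True)
class FeatureCloudSpec:
    """Gaussian-mixture cloud emulating pooled patch descriptors (default
    dimension 1280, the width of a typical pooled CNN embedding)."""

    n_points: int
    dim: int = 1280
    n_modes: int = 1
    mode_weights: tuple | None = None  # None → uniform
    mode_separation: float = 10.0
    within_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_points <= 0:
            raise ValueError("n_points must be positive")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.mode_weights is not None:
            wts = np.asarray(self.mode_weights, dtype=float)
            if wts.shape != (self.n_modes,) or not np.isclose(wts.sum(), 1.0):
                raise ValueError("mode_weights must be a length-n_modes simplex vector")
        if self.mode_separation < 0 or self.within_sd < 0:
            raise ValueError("scales must be nonnegative")


def generate_feature_cloud(spec: FeatureCloudSpec):
    """Draw a FeaturePool from a Gaussian mixture.

    Mode centers are i.i.d. N(0, mode_separation²) per coordinate, rows are
    center + N(0, within_sd²) noise.  The true mode of each row is recorded in
    the provenance table (column ``mode``) for test diagnostics.
    """
    from .negative_mining import FeaturePool

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    weights = (np.full(spec.n_modes, 1.0 / spec.n_modes)
               if spec.mode_weights is None else np.asarray(spec.mode_weights, dtype=float))
    centers = rng.normal(0.0, spec.mode_separation, (spec.n_modes, spec.dim))
    labels = rng.choice(spec.n_modes, size=spec.n_points, p=weights)
    features = centers[labels]
    if spec.within_sd > 0:
        features = features + rng.normal(0.0, spec.within_sd, (spec.n_points, spec.dim))
    else:
        features = features.copy()
    prov = pd.DataFrame({
        "slide_id": np.repeat("synthetic-cloud", spec.n_points),
        "x": np.arange(spec.n_points), "y": np.zeros(spec.n_points, dtype=int),
        "mode": labels,
    })
    return FeaturePool(features=features, provenance=prov,
                       pooling_tag="gaussian-mixture-synthetic")


# ---------------------------------------------------------------------------
# Slide I/O: PNG rasters, GeoJSON annotations, manifest CSV.

def polygons_to_geojson(polygons: Sequence, slide_id: str) -> dict:
    features = []
    for poly in polygons:
        ring = ccw_vertices(poly)
        coords = [[float(x), float(y)] for x, y in ring]
        if coords and coords[0] != coords[-1]:
            coords.append(coords[0])
        features.append({
            "type": "Feature",
            "properties": {"slide_id": slide_id, "class": "tumor_bed"},
            "geometry": {"type": "Polygon", "coordinates": [coords]},
        })
    return {"type": "FeatureCollection", "features": features}


def geojson_to_polygons(doc: dict) -> list[np.ndarray]:
    polys = []
    for feat in doc.get("features", []):
        ring = feat["geometry"]["coordinates"][0]
        arr = np.asarray(ring, dtype=float)
        if len(arr) > 1 and np.allclose(arr[0], arr[-1]):
            arr = arr[:-1]
        polys.append(arr)
    return polys


def save_slide(slide: SyntheticSlide, out_dir: str | Path, slide_id: str) -> dict:
    """Write image/mask PNGs and the GeoJSON annotation; return a manifest row."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"{slide_id}.png"
    mask_path = out / f"{slide_id}_mask.png"
    ann_path = out / f"{slide_id}.geojson"
    iio.imwrite(img_path, slide.image)
    iio.imwrite(mask_path, (slide.tumor_mask.astype(np.uint8) * 255))
    ann_path.write_text(json.dumps(
        polygons_to_geojson(slide.spec.tumor_polygons, slide_id),
        sort_keys=True, indent=1))
    return {"slide_id": slide_id, "path": str(img_path), "mask_path": str(mask_path),
            "annotation_path": str(ann_path), "label": slide.slide_label,
            "mpp": slide.spec.mpp, "width_px": slide.spec.width_px,
            "height_px": slide.spec.height_px}


def save_cohort(specs: Sequence[SlideSpec], out_dir: str | Path) -> pd.DataFrame:
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(specs):
        slide = generate_slide(spec)
        rows.append(save_slide(slide, out_dir, f"slide_{i:03d}"))
    manifest = pd.DataFrame(rows, columns=["slide_id", "path", "mask_path",
                                           "annotation_path", "label", "mpp",
                                           "width_px", "height_px"])
    manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return manifest
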