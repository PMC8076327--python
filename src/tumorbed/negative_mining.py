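"""Hard-negative mining from tumor-free slide regions.

Patches extracted entirely outside the annotated tumor bed are cancer-free by
definition, which makes them a cheap and abundant source of negatives — ink,
creases, blur, red blood cells, benign tissue — that curated datasets rarely
cover.  The pool is far too large to use wholesale, so it is subsampled
either uniformly at random or, better, by clustering pooled patch descriptors
with mini-batch K-means and drawing a fixed number of instances per cluster
(the reference configuration is 3000 clusters × 7 instances = 21,000).
Per-cluster sampling covers rare appearance modes that uniform sampling
misses.  Cluster-count choice is guided by the elbow of the explained-
variance curve, EV(k) = 1 − SSW(k)/SST.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, box
from sklearn.cluster import MiniBatchKMeans

from .preprocess import HsvBounds, hsv_foreground_mask, tile_slide

_MAGIC = b"TBFP"


@dataclass
class FeaturePool:
    """N×D descriptor matrix with per-row provenance (slide_id, x, y)."""

    features: np.ndarray
    provenance: pd.DataFrame
    pooling_tag: str = ""

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be an N×D matrix")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite entries")
        if len(self.provenance) != len(self.features):
            raise ValueError("provenance length must equal feature row count")

    def __len__(self) -> int:
        return self.features.shape[0]

    def save(self, prefix: str | Path) -> None:
        """Two-file pair: row-major float64 matrix with an (N, D) header,
        plus a provenance CSV."""
        prefix = Path(prefix)
        n, d = self.features.shape
        with open(prefix.with_suffix(".features.bin"), "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<qq", n, d))
            fh.write(np.ascontiguousarray(self.features).tobytes())
        self.provenance.to_csv(prefix.with_suffix(".provenance.csv"), index=False)

    @classmethod
    def load(cls, prefix: str | Path, pooling_tag: str = "") -> "FeaturePool":
        prefix = Path(prefix)
        with open(prefix.with_suffix(".features.bin"), "rb") as fh:
            if fh.read(4) != _MAGIC:
                raise ValueError("not a FeaturePool matrix file")
            n, d = struct.unpack("<qq", fh.read(16))
            feats = np.frombuffer(fh.read(), dtype=np.float64).reshape(n, d)
        prov = pd.read_csv(prefix.with_suffix(".provenance.csv"))
        return cls(features=feats.copy(), provenance=prov, pooling_tag=pooling_tag)


@dataclass
class ClusterModel:
    k: int
    centers: np.ndarray
    assignment: np.ndarray
    explained_variance: float
    inertia: float


# ---------------------------------------------------------------------------
# Candidate pooling

def tumor_bed_hull(polygons: Sequence) -> shapely.Geometry | None:
    """Convex hull of all annotation vertices; None when no annotation."""
    pts = [tuple(p) for poly in polygons for p in np.asarray(poly, dtype=float)]
    if not pts:
        return None
    return MultiPoint(pts).convex_hull


def pool_negatives(slides: Mapping[str, np.ndarray],
                   annotations: Mapping[str, Sequence],
                   patch_px: int, stride_px: int,
                   min_fg: float = 0.25,
                   bounds: HsvBounds | None = None) -> pd.DataFrame:
    """Candidate negative tiles: kept foreground tiles whose windows have
    zero area of intersection with the slide's tumor-bed convex hull.

    The hull (rather than the raw annotation) is used so that candidates are
    conservatively far from any annotated cancer.  Every slide must have an
    annotation entry (possibly an empty list).
    """
    rows = []
    for slide_id, image in slides.items():
        if slide_id not in annotations:
            raise KeyError(f"slide {slide_id!r} has no annotation entry")
        mask = hsv_foreground_mask(image, bounds)
        grid = tile_slide(mask.shape, patch_px, stride_px, mask, min_fg)
        kept = grid.kept
        hull = tumor_bed_hull(annotations[slide_id])
        if hull is not None and len(kept):
            boxes = shapely.box(kept["x"].to_numpy(dtype=float),
                                kept["y"].to_numpy(dtype=float),
                                kept["x"].to_numpy(dtype=float) + patch_px,
                                kept["y"].to_numpy(dtype=float) + patch_px)
            overlap = shapely.area(shapely.intersection(boxes, hull))
            kept = kept[overlap <= 0.0]
        for _, t in kept.iterrows():
            rows.append({"slide_id": slide_id, "x": int(t["x"]), "y": int(t["y"]),
                         "foreground_ratio": float(t["foreground_ratio"])})
    return pd.DataFrame(rows, columns=["slide_id", "x", "y", "foreground_ratio"])


def color_texture_descriptor(patch: np.ndarray) -> np.ndarray:
    """Handcrafted patch descriptor: joint HSV histogram + gradient-energy
    statistics.  A deliberately simple stand-in for pooled CNN embeddings,
    provided only so the mining pipeline can run end to end."""
    from skimage.color import rgb2hsv

    hsv = rgb2hsv(np.asarray(patch))
    hist, _ = np.histogramdd(hsv.reshape(-1, 3), bins=(8, 4, 4),
                             range=((0, 1), (0, 1), (0, 1)))
    hist = hist.ravel() / hist.sum()
    gy, gx = np.gradient(hsv[..., 2])
    grad = np.hypot(gx, gy)
    ghist, _ = np.histogram(grad, bins=8, range=(0, 0.5))
    stats = np.array([grad.mean(), grad.std(), hsv[..., 1].mean(), hsv[..., 2].mean()])
    return np.concatenate([hist, ghist / max(1, grad.size), stats])


def extract_features(slides: Mapping[str, np.ndarray], candidates: pd.DataFrame,
                     patch_px: int,
                     descriptor: Callable[[np.ndarray], np.ndarray] | None = None,
                     pooling_tag: str = "color-texture") -> FeaturePool:
    """Run a descriptor over every candidate window and assemble a pool."""
    desc = descriptor or color_texture_descriptor
    feats = []
    for _, row in candidates.iterrows():
        img = slides[row["slide_id"]]
        x, y = int(row["x"]), int(row["y"])
        feats.append(desc(img[y:y + patch_px, x:x + patch_px]))
    features = (np.stack(feats) if feats
                else np.zeros((0, 1), dtype=np.float64))
    return FeaturePool(features=features,
                       provenance=candidates[["slide_id", "x", "y"]].reset_index(drop=True),
                       pooling_tag=pooling_tag)


# ---------------------------------------------------------------------------
# Clustering

def _as_matrix(pool) -> np.ndarray:
    return pool.features if isinstance(pool, FeaturePool) else np.asarray(pool, dtype=np.float64)


def _chunked_inertia(X: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
    ssw = 0.0
    for start in range(0, len(X), 4096):
        chunk = X[start:start + 4096]
        diff = chunk - centers[labels[start:start + 4096]]
        ssw += float(np.einsum("ij,ij->", diff, diff))
    return ssw


def _repair_empty_clusters(X: np.ndarray, centers: np.ndarray,
                           labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Move each empty center onto the point farthest from its current
    center (among clusters that can spare one), so every cluster is
    nonempty.  Strictly reduces inertia."""
    k = centers.shape[0]
    counts = np.bincount(labels, minlength=k)
    empties = np.flatnonzero(counts == 0)
    if len(empties) == 0:
        return centers, labels
    centers = centers.copy()
    labels = labels.copy()
    dist2 = np.einsum("ij,ij->i", X - centers[labels], X - centers[labels])
    order = np.argsort(dist2)[::-1]
    ptr = 0
    for j in empties:
        while ptr < len(order) and counts[labels[order[ptr]]] <= 1:
            ptr += 1
        if ptr >= len(order):  # fewer spare points than empty clusters
            raise ValueError("cannot repair empty clusters: k exceeds distinct support")
        idx = order[ptr]
        counts[labels[idx]] -= 1
        centers[j] = X[idx]
        labels[idx] = j
        counts[j] = 1
        ptr += 1
    return centers, labels


def fit_minibatch_kmeans(pool, k: int, batch_size: int = 1024, seed: int = 0,
                         n_restarts: int = 3, max_iter: int = 100,
                         init: str = "auto") -> ClusterModel:
    """Mini-batch K-means with restarts, returning explained variance.

    EV = 1 − SSW/SST where SST is the total sum of squares about the global
    mean; a zero-variance pool has EV = 1 by convention.  ``n_restarts``
    independent fits are run and the one with the lowest full-pool inertia is
    kept, which tames optimizer noise on elbow curves.  ``init='auto'`` uses
    k-means++ for small k and random init for large k (k-means++ seeding cost
    grows with k).  Empty clusters are repaired after fitting so that every
    cluster has at least one member.
    """
    X = _as_matrix(pool)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty pool")
    if k > n:
        raise ValueError(f"k={k} exceeds pool size {n}")
    if k < 1:
        raise ValueError("k must be >= 1")

    mean = X.mean(axis=0)
    sst = float(np.einsum("ij,ij->", X - mean, X - mean))

    if k == n:
        centers = X.copy()
        labels = np.arange(n)
        ssw = 0.0
    else:
        init_method = init if init != "auto" else ("k-means++" if k <= 100 else "random")
        best = None
        for r in range(max(1, n_restarts)):
            km = MiniBatchKMeans(n_clusters=k, batch_size=batch_size,
                                 n_init=1, init=init_method, max_iter=max_iter,
                                 random_state=seed + r)
            km.fit(X)
            labels_r = km.predict(X)
            centers_r, labels_r = _repair_empty_clusters(X, km.cluster_centers_, labels_r)
            ssw_r = _chunked_inertia(X, centers_r, labels_r)
            if best is None or ssw_r < best[0]:
                best = (ssw_r, centers_r, labels_r)
        ssw, centers, labels = best

    ev = 1.0 if sst == 0.0 else float(np.clip(1.0 - ssw / sst, 0.0, 1.0))
    return ClusterModel(k=k, centers=centers, assignment=labels,
                        explained_variance=ev, inertia=ssw)


@dataclass
class ElbowResult:
    ks: list[int]
    explained_variance: list[float]
    knee_k: int

    @property
    def points(self) -> list[tuple[int, float]]:
        return list(zip(self.ks, self.explained_variance))


def elbow_curve(pool, k_grid: Sequence[int], seed: int = 0, **fit_kw) -> ElbowResult:
    """Explained-variance curve over ``k_grid`` plus the knee k.

    The knee is the grid point with maximum perpendicular distance to the
    chord joining the first and last curve points, computed after scaling
    both axes to [0, 1] so the choice is aspect-independent.
    """
    ks = list(k_grid)
    if ks != sorted(ks) or len(set(ks)) != len(ks):
        raise ValueError("k_grid must be strictly increasing")
    n = len(_as_matrix(pool))
    if any(k > n for k in ks):
        raise ValueError("k_grid contains k larger than the pool")
    evs = [fit_minibatch_kmeans(pool, k, seed=seed, **fit_kw).explained_variance
           for k in ks]
    knee = ks[_knee_index(np.asarray(ks, dtype=float), np.asarray(evs))]
    return ElbowResult(ks=ks, explained_variance=evs, knee_k=knee)


def _knee_index(ks: np.ndarray, evs: np.ndarray) -> int:
    if len(ks) < 3:
        return 0
    kx = (ks - ks[0]) / max(ks[-1] - ks[0], 1e-12)
    ky = (evs - evs[0]) / max(abs(evs[-1] - evs[0]), 1e-12)
    # distance from (kx, ky) to the chord (0,0)–(1, ky[-1]/|Δ|)
    p0 = np.array([kx[0], ky[0]])
    p1 = np.array([kx[-1], ky[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    rel = np.column_stack([kx, ky]) - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    return int(np.argmax(dist))


# ---------------------------------------------------------------------------
# Subsampling

def sample_by_cluster(model: ClusterModel, per_cluster: int = 7,
                      seed: int = 0) -> np.ndarray:
    """Exactly ``k × per_cluster`` row indices, uniform without replacement
    within each cluster; clusters smaller than the quota are sampled with
    replacement so the total count is exact."""
    if per_cluster < 1:
        raise ValueError("per_cluster must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for c in range(model.k):
        members = np.flatnonzero(model.assignment == c)
        if len(members) == 0:
            raise ValueError(f"cluster {c} has no members; cannot sample")
        replace = len(members) < per_cluster
        out.append(rng.choice(members, size=per_cluster, replace=replace))
    return np.concatenate(out)


def sample_random(pool, n: int, seed: int = 0) -> np.ndarray:
    """Uniform sample of ``n`` row indices without replacement."""
    size = len(_as_matrix(pool))
    if n > size:
        raise ValueError(f"cannot sample {n} rows from a pool of {size}")
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    return rng.choice(size, size=n, replace=False)
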