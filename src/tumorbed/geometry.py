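"""Shared polygon utilities.

Coordinate convention used throughout the package: a pixel at row ``r``,
column ``c`` of a raster has its center at the point ``(x=c, y=r)``.  A pixel
belongs to a polygon iff the polygon covers its center (boundary inclusive).
"""

from __future__ import annotations

import math

import numpy as np
import shapely
from shapely.geometry import Polygon


def as_polygon(vertices) -> Polygon:
    """Build a shapely polygon from an (n, 2) array of (x, y) vertices."""
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("polygon needs an (n>=3, 2) array of (x, y) vertices")
    poly = Polygon(arr)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def ccw_vertices(vertices) -> np.ndarray:
    """Return the ring in counter-clockwise orientation (y-up convention)."""
    arr = np.asarray(vertices, dtype=float)
    x, y = arr[:, 0], arr[:, 1]
    # shoelace signed area; positive = CCW
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return arr if area2 >= 0 else arr[::-1]


def rasterize_polygon(vertices, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon to a boolean mask of ``shape`` (H, W).

    Pixel-center containment: mask[r, c] is True iff the polygon covers the
    point (c, r), boundary included.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    arr = np.asarray(vertices, dtype=float)
    if arr.size == 0:
        return mask
    poly = as_polygon(arr)
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(0, math.floor(minx))
    c1 = min(w - 1, math.ceil(maxx))
    r0 = max(0, math.floor(miny))
    r1 = min(h - 1, math.ceil(maxy))
    if c1 < c0 or r1 < r0:
        return mask
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    cc, rr = np.meshgrid(cols, rows)
    pts = shapely.points(cc.ravel(), rr.ravel())
    shapely.prepare(poly)
    inside = shapely.covers(poly, pts).reshape(rr.shape)
    mask[r0:r1 + 1, c0:c1 + 1] = inside
    return mask


def random_convex_polygon(rng: np.random.Generator, center, radius: float,
                          n_points: int = 12,
                          r_range: tuple[float, float] = (0.3, 1.0)) -> np.ndarray:
    """Random convex polygon: convex hull of points in an annulus, as CCW
    (x, y).  ``r_range`` sets the radial spread; a high floor gives rounder,
    blob-like shapes."""
    from scipy.spatial import ConvexHull

    ang = rng.uniform(0, 2 * np.pi, n_points)
    rad = radius * np.sqrt(rng.uniform(r_range[0], r_range[1], n_points))
    pts = np.column_stack([center[0] + rad * np.cos(ang),
                           center[1] + rad * np.sin(ang)])
    hull = ConvexHull(pts)
    return ccw_vertices(pts[hull.vertices])


def polygon_in_bounds(vertices, width: int, height: int) -> bool:
    arr = np.asarray(vertices, dtype=float)
    return bool(np.all(arr[:, 0] >= 0) and np.all(arr[:, 0] <= width - 1)
                and np.all(arr[:, 1] >= 0) and np.all(arr[:, 1] <= height - 1))
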