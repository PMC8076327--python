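import numpy as np
import pytest
import shapely
from shapely.geometry import LineString, Polygon

from tumorbed import (
    convex_hull,
    d_prim,
    dice,
    evaluate_cohort,
    longest_diagonal,
    longest_perpendicular,
    px_to_mm,
    tumor_bed,
)
from tests.conftest import random_convex_polys


def gift_wrap(points):
    """O(n²) gift-wrapping hull oracle, CCW vertex list."""
    pts = np.unique(np.asarray(points, float), axis=0)
    start = min(range(len(pts)), key=lambda i: (pts[i][0], pts[i][1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % len(pts)
        for j in range(len(pts)):
            if j == cur:
                continue
            a = pts[cand] - pts[cur]
            b = pts[j] - pts[cur]
            cross = a[0] * b[1] - a[1] * b[0]
            if cross > 0 or (cross == 0
                             and np.linalg.norm(pts[j] - pts[cur])
                             > np.linalg.norm(pts[cand] - pts[cur])):
                cand = j
        if cand == start:
            break
        hull.append(cand)
    return pts[hull]


def chord_scan_oracle(hull, endpoints, resolution=1e-3):
    """Dense perpendicular-chord scan via shapely line clipping."""
    pts = np.asarray(hull, float)
    p, q = np.asarray(endpoints[0]), np.asarray(endpoints[1])
    u = (q - p) / np.linalg.norm(q - p)
    n = np.array([-u[1], u[0]])
    rot = np.column_stack([pts @ u, pts @ n])
    poly = Polygon(rot)
    x0, y0, x1, y1 = poly.bounds
    best = 0.0
    for x in np.arange(x0, x1, resolution * (x1 - x0) if x1 > x0 else 1):
        seg = shapely.intersection(poly, LineString([(x, y0 - 1), (x, y1 + 1)]))
        best = max(best, seg.length)
    return best


class TestConvexHull:
    def test_square_corners(self):
        pts = [(0, 0), (2, 0), (2, 2), (0, 2)]
        hull = convex_hull(np.array(pts, float))
        assert {tuple(v) for v in hull} == {(0, 0), (2, 0), (2, 2), (0, 2)}

    def test_interior_points_do_not_change_hull(self):
        rng = np.random.default_rng(0)
        corners = np.array([(0, 0), (10, 0), (10, 10), (0, 10)], float)
        interior = rng.uniform(1, 9, (30, 2))
        hull = convex_hull(np.vstack([corners, interior]))
        assert {tuple(v) for v in hull} == {tuple(v) for v in corners}

    def test_matches_gift_wrapping_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(200, 2)) * 50
        ours = {tuple(np.round(v, 9)) for v in convex_hull(pts)}
        oracle = {tuple(np.round(v, 9)) for v in gift_wrap(pts)}
        assert ours == oracle

    def test_degenerate_inputs(self):
        assert convex_hull(np.zeros((0, 2))).shape == (0, 2)
        assert len(convex_hull(np.array([[3.0, 4.0]]))) == 1
        collinear = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        hull = convex_hull(collinear)
        assert len(hull) == 2
        assert {tuple(v) for v in hull} == {(0, 0), (3, 3)}

    def test_mask_input_uses_pixel_centers(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 3:7] = True
        hull = convex_hull(mask)
        assert hull[:, 0].min() == 3 and hull[:, 0].max() == 6
        assert hull[:, 1].min() == 2 and hull[:, 1].max() == 4


class TestDiagonals:
    def test_unit_square_d1_d2(self):
        square = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], float)
        d1, endpoints = longest_diagonal(square)
        assert d1 == pytest.approx(np.sqrt(2))
        assert longest_perpendicular(square, endpoints) == pytest.approx(np.sqrt(2))

    def test_single_point_and_segment(self):
        d1, ep = longest_diagonal(np.array([[2.0, 3.0]]))
        assert d1 == 0.0
        seg = np.array([[0.0, 0.0], [5.0, 0.0]])
        d1, ep = longest_diagonal(seg)
        assert d1 == 5.0
        assert longest_perpendicular(seg, ep) == 0.0

    def test_d1_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(2)
        for hull in random_convex_polys(60, rng):
            d1, _ = longest_diagonal(hull)
            pairwise = np.linalg.norm(hull[:, None] - hull[None, :], axis=-1)
            assert d1 == pytest.approx(pairwise.max(), rel=1e-12)

    def test_d2_matches_chord_scan_oracle(self):
        rng = np.random.default_rng(3)
        for hull in random_convex_polys(25, rng):
            d1, endpoints = longest_diagonal(hull)
            d2 = longest_perpendicular(hull, endpoints)
            oracle = chord_scan_oracle(hull, endpoints)
            assert d2 >= oracle - 1e-9   # scan is a lower bound
            assert d2 == pytest.approx(oracle, rel=5e-3)

    def test_sandwich_and_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        for hull in random_convex_polys(40, rng):
            d1, ep = longest_diagonal(hull)
            d2 = longest_perpendicular(hull, ep)
            dp = d_prim(d1, d2)
            assert d2 <= dp + 1e-9 <= d1 + 2e-9
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
            moved = hull @ rot.T + rng.uniform(-100, 100, 2)
            m1, mep = longest_diagonal(moved)
            m2 = longest_perpendicular(moved, mep)
            assert m1 == pytest.approx(d1, rel=1e-9)
            assert m2 == pytest.approx(d2, rel=1e-9)

    def test_lengths_scale_linearly(self):
        rng = np.random.default_rng(5)
        hull = random_convex_polys(1, rng)[0]
        d1, ep = longest_diagonal(hull)
        d2 = longest_perpendicular(hull, ep)
        s1, sep = longest_diagonal(hull * 3.5)
        s2 = longest_perpendicular(hull * 3.5, sep)
        assert s1 == pytest.approx(3.5 * d1)
        assert s2 == pytest.approx(3.5 * d2)

    def test_regular_polygon_approaches_circle_diameter(self):
        ang = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        ngon = np.column_stack([10 * np.cos(ang), 10 * np.sin(ang)])
        d1, ep = longest_diagonal(ngon)
        d2 = longest_perpendicular(ngon, ep)
        for val in (d1, d2, d_prim(d1, d2)):
            assert val == pytest.approx(20.0, rel=5e-3)


class TestDPrim:
    def test_geometric_mean_identity(self):
        assert d_prim(7.0, 7.0) == 7.0
        assert d_prim(4.0, 0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            d_prim(-1.0, 2.0)

    def test_unit_conversion(self):
        assert px_to_mm(2000, 0.5) == pytest.approx(1.0)

    def test_tumor_bed_from_mask_in_mm(self):
        mask = np.zeros((300, 300), bool)
        mask[50:251, 50:251] = True  # 200-px square of pixel centers
        tb = tumor_bed(mask, mpp=5.0)
        assert tb.d1_px == pytest.approx(200 * np.sqrt(2))
        assert tb.d_prim_mm == pytest.approx(200 * np.sqrt(2) * 5 / 1000)


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((5, 5), bool)
        m[1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5), bool)
        b = np.zeros((5, 5), bool)
        a[0, 0] = True
        b[4, 4] = True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 8), bool)
        b = np.zeros((4, 8), bool)
        a[:, :4] = True
        b[:, 2:6] = True
        assert dice(a, b) == 0.5

    def test_empty_conventions(self):
        empty = np.zeros((3, 3), bool)
        full = ~empty
        assert dice(empty, empty) == 1.0
        assert dice(empty, full) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2)), np.zeros((3, 3)))


class TestEvaluateCohort:
    def test_self_comparison_is_perfect(self, square_slide):
        masks = {"a": square_slide.tumor_mask}
        report = evaluate_cohort(masks, masks, mpp=1.0)
        assert report.mean_dice >= 0.99
        assert report.mean_abs_error_mm == pytest.approx(0.0)
        assert report.confusion.tolist() == [[0, 0], [0, 1]]

    def test_empty_predictions_score_ground_truth_extent(self, square_slide):
        empty = np.zeros_like(square_slide.tumor_mask)
        report = evaluate_cohort({"a": empty}, {"a": square_slide.tumor_mask}, 1.0)
        row = report.per_slide.iloc[0]
        assert row["dice"] == 0.0
        gt_dprim = tumor_bed(square_slide.tumor_mask, 1.0).d_prim_mm
        assert row["abs_error_mm"] == pytest.approx(gt_dprim)
        assert report.confusion.tolist() == [[0, 0], [1, 0]]

    def test_tumor_free_agreement_is_true_negative(self):
        empty = np.zeros((10, 10), bool)
        report = evaluate_cohort({"a": empty}, {"a": empty}, 1.0)
        assert report.per_slide.iloc[0]["dice"] == 1.0
        assert report.confusion.tolist() == [[1, 0], [0, 0]]

    def test_confusion_entries_sum_to_cohort_size(self, square_slide):
        empty = np.zeros_like(square_slide.tumor_mask)
        preds = {"a": square_slide.tumor_mask, "b": empty, "c": empty}
        gts = {"a": square_slide.tumor_mask, "b": square_slide.tumor_mask, "c": empty}
        report = evaluate_cohort(preds, gts, 1.0)
        assert report.confusion.sum() == 3
        assert len(report.per_slide) == 3

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_cohort({"a": np.zeros((2, 2))}, {"b": np.zeros((2, 2))}, 1.0)
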