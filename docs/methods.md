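# Methods

## Problem setting

After neoadjuvant therapy, the residual tumor bed on a resection slide is
defined as the convex hull containing all remaining cancer cells. Its
physical extent predicts long-term outcome, so the quantity of interest is
not an overlap percentage but a length in millimeters. The package measures
extent with d1, the longest diagonal of the hull; d2, the longest chord of
the hull perpendicular to d1; and their geometric mean d_prim = √(d1·d2).
d_prim preserves scale (a missed 40 mm bed and a missed single cell both
have Dice 0 but very different d_prim errors) and is extremely sensitive to
distant false positives, which drag the hull outward.

## Pipeline model and assumptions

A binary patch classifier p(x) ∈ [0, 1] is the only learned component, and
it is deliberately *pluggable*: the package ships a ground-truth oracle and
a color-box scorer for testing, and any callable mapping a batch of
H×W×3 patches to probabilities can be registered. Everything around the
classifier is deterministic:

1. **Tissue mask.** A pixel is foreground iff 0.5 < hue < 0.65,
   saturation > 0.1, 0.5 < value < 0.9 in HSV. The comparison operators are
   strict for hue/saturation/value and inclusive for the tile-level
   foreground-ratio cut (≥ 25%), matching the stated bounds exactly. The
   mask is computed at the working resolution of the supplied raster; no
   pyramid-level propagation is attempted (synthetic slides are
   single-level), though callers may downsample before masking.
2. **Tiling.** Half-open windows [x, x+P) × [y, y+P) at stride s, 0-based
   origins at multiples of s, windows fully inside the slide (overhanging
   edge tiles are dropped rather than padded — the tile count per axis is
   ⌊(W−P)/s⌋+1).
3. **Voting.** Each kept tile's probability is added over its window and a
   vote counter incremented; the heatmap is the vote-weighted mean, so an
   interior pixel receives (P/s)² votes when s divides P. Pixels covered
   only by skipped background tiles keep zero votes and can never be
   positive.
4. **Calls.** A pixel is positive iff it has votes and mean ≥ threshold
   (default 0.5, inclusive, deliberately not tunable against a test set); a
   *tile* is positive by its own probability, and the slide is
   tumor-positive iff at least one tile is positive. The hull is built from
   the averaged pixel mask; both the tile-level and pixel-level positive
   sets are reported.

## Negative mining

Patches wholly outside the annotated tumor bed are cancer-free by
definition. Candidates are kept foreground tiles whose windows have zero
intersection *area* with the convex hull of the annotation (the hull, not
the raw outline, to stay conservative; windows merely touching the hull
boundary are kept). Subsampling is either uniform or per-cluster after
mini-batch K-means on patch descriptors:

- Explained variance EV(k) = 1 − SSW/SST, with EV := 1 for a zero-variance
  pool (limit convention). The elbow of EV(k) guides k; the knee is the
  grid point with maximal perpendicular distance to the first–last chord
  after scaling both axes to [0, 1] (the knee is advisory — k remains a
  parameter).
- The fit runs a configurable number of restarts (default 3) and keeps the
  lowest full-pool inertia, which makes EV(k) monotone in practice.
  k-means++ seeding costs O(k·n·d), so initialization switches to random
  above k = 100 ("auto" mode).
- After fitting, empty clusters are repaired by moving each empty center
  onto the point currently farthest from its assigned center (among
  clusters that can spare one). This strictly reduces inertia and
  guarantees the per-cluster sampler's contract of exactly k × per_cluster
  selections — e.g. 3000 × 7 = 21,000 — even on pools several orders of
  magnitude smaller than a production candidate set. Clusters smaller than
  the quota are sampled with replacement rather than shrinking the output.
- The shipped descriptor (joint HSV histogram + gradient-energy statistics,
  140-D) exists to exercise the contract end to end; production use is
  expected to plug in pooled CNN embeddings (the conventional 1280-D pooled
  embedding is the feature-cloud default dimension).

## Imbalance and augmentation

`class_weights` implements the three weighting modes with the standard
formulas w_c = K·N_c/N (proportional), w_c = N/(K·N_c) (inverse), w_c = 1
(equal); an optional normalization divides by the mean weight. The
oversampling plan uses r_c = max(1, round(N_max/N_c)) with an optional
global multiplier; published repetition counts for specific cohorts are not
always reconstructible from class totals, so the rule is exposed rather
than hard-coded constants.

Augmentation order is crop → affine → color jitter → resize. Shear is drawn
uniformly from [−60°, +60°] independently per axis (the magnitude bound
reading of "shear by 60°"); scale from [0.9, 1.1]; color jitter perturbs
brightness, contrast, saturation multiplicatively by ±5% and hue additively
by ±0.05, each independently uniform. Test-time augmentation always makes
variant 0 the deterministic center crop, so tta_n = 1 is reproducible;
further variants are random crops composed with flips and 90° rotations.

## Synthetic slides

The generator emulates, at ≤ 4096² px, the features of a post-treatment WSI
that this pipeline actually consumes: bright background (fails the
saturation/value bounds), a convex tissue blob painted inside the HSV
foreground box, zero or more convex tumor polygons painted in a
higher-hue/saturation band (separable by a color box), and parametric
artifacts — Gaussian ink blobs, disk-packed red-blood-cell fields,
random-walk creases, local box blur — drawn only outside the tumor, whose
pixels are restored afterwards so the ground-truth mask remains the exact
rasterization of the polygons (pixel-center, boundary-inclusive,
counter-clockwise GeoJSON rings). Default mpp = 1.0 µm/px keeps px↔mm
conversions round. Fixed seed ⇒ byte-identical output.

What it does *not* emulate: nucleus-level texture, stain variability,
pyramid file formats, non-convex or multifocal tumor beds with isolated
cells, and annotation noise. Passing tests therefore demonstrate the
correctness of the surrounding machinery — masking, tiling, voting,
geometry, sampling arithmetic — not the difficulty of real histology
classification, which lives entirely in the plugged-in classifier.

## Reference conditions and problem sizes

- Geometry oracles: 200 random convex polygons (4–50 vertices, radii
  5–200); d1 against all-pairs brute force (exact), d2 against a dense
  perpendicular chord scan at 10⁻³·d1 resolution (agreement within 0.5% —
  the scan undershoots by construction).
- End-to-end recovery: 10 slides at 1536², 70% tumor-positive (the
  tumor-free share mirrors a realistic post-treatment cohort), tumors
  spanning roughly 0.6–0.8 of the slide, oracle classifier at patch 24 /
  stride 12. Tile quantization dilates the predicted hull by ≈ patch/2 per
  side, so with patch ≈ 4% of tumor extent the analytic expectation is hull
  Dice ≈ 0.95–0.97 and d_prim inflation ≈ one patch length; the suite
  asserts mean hull Dice ≥ 0.95 and per-slide d_prim error ≤ 2 patch
  diagonals, with a diagonal slide-level confusion matrix.
- Mining at reference scale: a 25,000 × 1280 Gaussian-mixture pool stands
  in for a production candidate set when checking the 3000 × 7 = 21,000
  selection contract (single restart, capped epochs); elbow behaviour is
  verified on a 3-mode cloud where the knee must land at k = 3.

## Numerical choices and degenerate inputs

- d1 via rotating calipers over hull vertices (the diameter of a convex
  region is attained at vertices); ties broken toward the lexicographically
  smallest endpoint pair. d2 by rotating the hull so d1 is axis-aligned:
  the vertical extent of a convex polygon is concave piecewise-linear in x,
  so only vertex abscissae need evaluation.
- Degenerate hulls: empty input → empty hull with d1 = d2 = d_prim = 0; a
  single point → 0; collinear points → the extreme pair (d2 = 0).
- Dice(∅, ∅) := 1 and two empty masks count as a true negative;
  empty-vs-nonempty Dice is 0 and the d_prim error equals the nonempty
  side's extent. Cohort Dice is computed between rasterized convex hulls by
  default (`hullify=False` gives raw-mask Dice).
- Masks convert to geometry via pixel centers; px → mm as px · mpp / 1000.
- Probabilities outside [0, 1] from a plugged-in classifier are an error,
  not clipped.

## Known limitations

- The sliding-window accumulator stores full-resolution float64/int32
  planes; slides far beyond 4096² need the (approximate) downsampling hook
  at the caller level rather than the built-in accumulator.
- The elbow knee is heuristic; on curves without curvature it returns the
  first grid point.
- Per-cluster sampling with replacement can repeat rows when clusters are
  tiny; consumers needing distinct rows should deduplicate or lower the
  quota.
- The toy classifiers are intentionally trivial; no claim about real H&E
  classification performance follows from them.
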