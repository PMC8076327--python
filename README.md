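# tumorbed

A toolkit for estimating the **tumor bed** — the convex hull containing all
residual cancer — on whole-slide images (WSIs) of breast tissue resected
after neoadjuvant therapy, and for measuring how well an automated pipeline
recovers it.

Slide-wide cancer localization differs from patch classification: a single
distant false positive or missed isolated tumor cell can move the tumor-bed
boundary by centimeters, so the pipeline must be precise *everywhere* on the
slide. The package implements the full workflow around a pluggable binary
patch classifier:

- **HSV tissue masking and tiling** (`tumorbed.preprocess`): foreground =
  pixels with 0.5 < hue < 0.65, saturation > 0.1 and 0.5 < value < 0.9;
  patches with ≥ 25% foreground enter the model.
- **Hard-negative mining** (`tumorbed.negative_mining`): patches outside the
  annotated tumor bed are cancer-free by definition; the candidate pool is
  subsampled either at random or by mini-batch K-means over patch
  descriptors with a fixed quota per cluster (reference configuration:
  3000 clusters × 7 = 21,000 negatives), with elbow-based guidance on the
  explained-variance curve EV(k) = 1 − SSW(k)/SST.
- **Imbalance policies and augmentation** (`tumorbed.training_support`):
  proportional / inverse / equal loss weights, minority-oversampling plans
  r_c = round(N_max/N_c), the crop 512→448→224 + affine + 5% color-jitter
  augmentation pipeline, and test-time augmentation.
- **Sliding-window voting** (`tumorbed.slide_inference`): at stride s < patch
  P every interior pixel receives (P/s)² probability votes (512/256 → 4,
  512/16 → 1024) which are averaged into a heatmap; a slide is
  tumor-positive as soon as one patch is positive.
- **Extent metrics** (`tumorbed.tumorbed_eval`): the predicted region's
  convex hull is summarized by d1 (hull diameter, rotating calipers), d2
  (longest chord perpendicular to d1), and

      d_prim = sqrt(d1 · d2)   [mm]

  together with hull Dice overlap and a slide-level confusion matrix.
- **Synthetic slides** (`tumorbed.synthetic_slide`): reduced-scale WSIs with
  tissue, convex tumor regions, artifact textures (ink, blur, creases, red
  blood cells) and exact ground truth, so the whole pipeline runs and is
  tested without any proprietary slide data.

## Worked example

```python
import numpy as np
from tumorbed import (SlideSpec, generate_slide, predict_slide,
                      toy_classifier, evaluate_cohort)

square = np.array([[150, 150], [350, 150], [350, 350], [150, 350]], float)
slide = generate_slide(SlideSpec(width_px=512, height_px=512,
                                 tumor_polygons=(square,), seed=3))
clf = toy_classifier("oracle", tumor_mask=slide.tumor_mask)
pred = predict_slide(slide.image, clf, patch_px=64, stride_px=32)
report = evaluate_cohort({"demo": pred.tumor_mask},
                         {"demo": slide.tumor_mask}, mpp=1.0)
print(pred.slide_label, len(pred.positive_tiles))
print(report.per_slide[["dice", "gt_dprim_mm", "pred_dprim_mm"]].round(3))
```

prints

```
tumor-positive 64
    dice  gt_dprim_mm  pred_dprim_mm
0  0.667        0.283          0.363
```

The 200-px square tumor has d1 = d2 = 200√2 px, so its true extent is
d_prim = 0.283 mm at 1 µm/px. The oracle classifier marks every 64-px tile
touching the tumor, which dilates the predicted hull by up to half a patch
on each side — a large relative inflation for a tumor only ~3 patches wide,
hence the larger predicted extent and the modest hull Dice. The effect
shrinks as patch size falls relative to tumor extent: on the test suite's
cohort (tumors ~25–30 patches across at patch 24/stride 12) the same
pipeline recovers mean hull Dice ≥ 0.95 and d_prim errors below two patch
diagonals.

The same pipeline is scriptable from the shell:

```bash
tumorbed simulate --config config.yaml   # synthetic cohort + manifest
tumorbed mine     --config config.yaml   # negative pool → clusters → selection
tumorbed infer    --config config.yaml   # heatmaps, masks, slide labels
tumorbed evaluate --config config.yaml   # Dice, d_prim error, confusion matrix
```

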