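# Methods

## Acetabular index geometry

The acetabular index (AcI) of one hip is defined clinically as the angle
between the Hilgenreiner line (H-line) — through the two triradiate
cartilage centres — and the acetabular roof line from the triradiate
centre to the lateral edge of the acetabular sourcil. pelvikit represents
a radiograph's annotation as four landmarks in pixel coordinates
(x rightward, y downward, 0-based): RU/RD on the image-right side and
LU/LD on the image-left side, U = lateral acetabular edge, D = triradiate
centre. "Left/right" follow image-space position, matching the CVAT-style
annotation labels, not patient anatomy.

With `h = LD − RD` and per-side roof vector `m = U − D`, the index is

```
θ = atan2(|det(h, m)|, |h · m|) · 180/π .
```

Taking absolute values of both determinant and dot product makes θ the
acute angle between the two *lines*: it lies in [0°, 90°], is 0° when the
roof is parallel to the H-line (the clinically meaningful zero), and is
independent of the orientation chosen for either vector. A formulation
with the determinant and dot product interchanged would instead return
the complement of the clinical angle (90° at parallel), so the form above
is normative in this package. The same absolute-value construction makes
θ exactly invariant under rigid transforms and uniform scaling, and
mirror reflection plus side-swapping exchanges the two sides' angles
exactly; both properties are enforced by tests.

Degenerate inputs (coincident D points, or a side's U == D) raise a
dedicated error rather than returning NaN.

### Diagnosis rule

A side is called DDH iff its AcI ≥ threshold; the image is DDH iff any
side is. The threshold defaults to 30° — the approximate mean AcI of the
dysplastic class in infant screening data and the conventional clinical
cut-off in the first months of life — with the boundary inclusive (an
index exactly at the threshold is flagged, the conservative choice for a
screening tool). Both threshold and rule are explicit configuration, not
constants.

## Error metrics and aggregation

* **RMSE** pools all per-coordinate residuals (8 per case: x and y of 4
  landmarks) before the root; this is the interpretation under which RMSE
  is bounded above by the mean per-landmark pixel error.
* **Pixel error** is the per-landmark Euclidean distance; its scalar
  summary is the mean over landmarks and cases.
* **AcI error** is the per-side absolute difference between predicted and
  true index in degrees.

Result tables report mean, std and median per landmark (RU, RD, LU, LD)
or per side (Left, Right) and append an **Avg** row. The Avg row is the
unweighted column-wise mean of the per-key statistics — the convention
used in published per-landmark error tables, which this package's
aggregation reproduces arithmetically — rather than a pooled statistic;
a pooled mode is exposed for callers who want it (the two differ whenever
groups are unbalanced or stds differ). Std uses the sample (n − 1)
denominator and is defined as 0 for a single case. Quartiles in
five-number summaries use linear interpolation between closest ranks
(numpy's default percentile method). Exported tables are formatted to
3 decimals with round-half-even.

## Synthetic pelvis phantoms

The generator produces stylized stand-ins for infant AP pelvic
radiographs. Per side it draws three bright silhouettes on a dark
background:

* **ilium** — a triangle whose inferior edge *is* the acetabular roof
  line: the bottom-medial vertex is exactly D, the lateral vertex exactly
  U, with an apex above and between them (height 0.24 w at 35% of the
  roof span, w = pelvis width);
* **middle bone** (ischium-pubis) — an ellipse below the H-line;
* **femur** — a larger ellipse further inferolateral.

D points sit at ±0.30 w from the pelvis centre on the H-line and the
roof length is 0.22 w, so each side's roof line makes exactly the sampled
angle with the H-line. The whole scene is rotated by a global pose angle
about the pelvis centre; because the index is rotation-invariant, the
stored ground-truth angles are unaffected, and `compute_aci` on the
stored landmarks reproduces them to float precision (tested at 1e−6°).
An intensity gradient (slope per pixel row) and i.i.d. Gaussian noise are
added before 8-bit quantization. Masks, landmarks and angles are recorded
before any image degradation, so ground truth is exact.

Default canvas is 512 × 512 8-bit grayscale. Pose and nuisance
parameters are uniform draws: centre jitter ±15 px, width 280–340 px,
rotation ±5°, gradient 0–0.06 intensity/row, noise σ 3–8 (overridable,
e.g. 0 for noiseless phantoms). All randomness flows from integer seeds;
identical seeds give byte-identical images, annotations and manifests.
The dataset manifest stores every generator parameter at full precision
(`%.17g`), so a dataset reconstructs bit-for-bit from the manifest alone.

### Class-conditional angle distributions

Per-side angles are drawn from truncated normals anchored to the
five-number summaries of a 354-image infant screening population
(234 normal, 120 DDH — the default class mix):

| class  | loc  | scale | truncation      | resulting median / mean |
|--------|------|-------|-----------------|-------------------------|
| normal | 20.0 | 4.5   | [3.498, 33.479] | ≈ 19.99 / 19.98         |
| ddh    | 28.0 | 9.0   | [16.442, 61.932]| ≈ 29.13 / 29.75         |

Truncation bounds are the observed class min/max. The DDH location of
28.0 was chosen so that the *truncated* distribution reproduces the
observed class median (~28.9°) and mean (~30°) simultaneously: the
asymmetric truncation (lower bound 1.5 SD below the location, upper
3.5 SD above) supplies the strong right skew the clinical data show
(Q3 − median ≫ median − Q1). A location of 30 would push the truncated
median to ~30.7°, outside the observed value.

The two sides are sampled independently — no left/right correlation is
modelled. A consequence worth noting: a DDH-labelled phantom can have
both sides below the 30° threshold (the class marginal has median ≈ 29°),
so the class label is not always recoverable from the angles; diagnosis
accuracy is therefore meaningfully evaluated against the thresholded
ground-truth angles, and label-based confusion counts are reported as
context, not as a detector quality bound.

### What the phantoms do and do not emulate

They emulate: two-sided pelvis topology with four exactly-known
landmarks, class-conditional angle statistics, global pose variation,
intensity gradient and sensor-like noise, and the full annotation format
(COCO keypoints + polygons). They do not emulate: radiographic texture,
overlapping or ambiguous bone boundaries, unossified femoral heads,
age/sex anatomy covariates, or pixel spacing (geometry is defined in
pixels; no mm calibration exists). Passing tests therefore validate the
geometry, metrics, I/O and pipeline plumbing — not clinical detector
performance on real radiographs.

## Two-stage pipeline

Stage order is fixed: segmentation → binary-mask rendering → landmark
detection → geometry → diagnosis. The landmark detector receives only the
segmentation product (masks / the 0/255 binary image), never the raw
radiograph — the mask bridge is the point of the design, since a detector
trained on binary silhouettes is insulated from intensity variation. The
binary bridge is pure 0/255 foreground (the stricter reading of "binary
masked image"), not a masked copy of the grayscale.

### Classical backend

Segmentation: Otsu global threshold (computed on the native integer
image — exact histogram bins keep the cut on the correct side of the
background mode's top value), binary opening with a radius-1 disk,
connected components with a 60 px minimum area, then assignment:
components are split left/right of the mean component-centroid x, and per
side the three largest are ordered top-to-bottom as ilium, middle bone,
femur.

Landmark rules operate on the ilium masks only: D is the mean pixel of
the mask's medial-most occupied column, U the mean pixel of its
lateral-most column. The phantom ilium is built so those corners are the
true landmarks; the rules are exactly translation-equivariant and move
≤ ~1 px under one-pixel mask dilation. Residual error (~2.3 px mean on
noiseless phantoms) comes from rasterization and the corner rounding
introduced by the morphological opening; the triradiate proxies (RD/LD)
dominate because the D corner is the sharpest. The resulting AcI error is
~1.1° on average (roof length ≈ 66 px, so 2 px of landmark error ≈ 1.7°),
which keeps diagnosis agreement at 100% for cases whose true angles are
at least 5° from the threshold.

The classical backend's mean pixel error is non-decreasing in phantom
noise σ over {0, 5, 10, 20} (averaged over 50 seeds); in practice it is
nearly flat, because the bone/background contrast (~150 intensity levels)
keeps Otsu thresholding stable far beyond σ = 20 and the opening removes
isolated flipped pixels.

### Oracle and neural backends

The oracle backend returns the stored ground truth and must produce
exactly zero RMSE and all-zero error tables end to end — a plumbing
identity test, enforced in the acceptance suite. The neural backend is a
declared interface for Mask R-CNN / Keypoint R-CNN detectors; the config
schema carries the standard training hyperparameters (RPN batch size 256,
ROI-heads batch size 128, base LR 7.5e-4, 2500 iterations, weight decay
1e-4, batch size 4) so a trained implementation can slot in, but no
weights ship and instantiating it raises a configuration error.

## Annotation I/O and splitting

COCO 1.0 files carry three polygon categories (ilium, middle, femur; the
side is a per-annotation attribute, since the bone classes are the
categories) and one keypoint category with keypoints (RU, RD, LU, LD) in
fixed order, visibility flag 2 (labeled and visible — the landmarks are
always visible on these images). Readers accept both the canonical short
names and CVAT position labels ("left up" → LU, etc.); schema violations
report the offending image id. Writing is deterministic (sorted ids,
sorted keys, no timestamps).

The dataset split shuffles ids with a seeded generator and allocates
round(0.7 n) / round(0.1 n) to train/val (round-half-even) with the
remainder to test, giving (248, 35, 71) at n = 354. Splits are
unstratified by default (stratification was not part of the protocol
being mirrored); partitions are disjoint, exhaustive and
seed-reproducible.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use phantom sets of 12–120
cases, 1000 phantoms for angle-recovery checks, 10,000 draws per class
for sampler medians, and 50 seeds per noise level for the degradation
sweep — sizes at which every statistical check is stable while the whole
suite runs in well under a minute on one core.

## Known limitations

* Phantoms are geometric silhouettes; no claim transfers to real
  radiograph appearance.
* The classical backend's landmark rules are tailored to the phantom's
  ilium construction; on real masks a trained detector is required.
* Only the acetabular index is implemented — no Sharp angle, lateral
  centre-edge angle, or ultrasound (Graf) geometry.
* Angles are unitless pixel-plane measurements; absolute distances (mm)
  are unavailable without pixel-spacing metadata.
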