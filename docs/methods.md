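# Methods

This note documents the models and procedures implemented in `acnekit`, the
choices behind them, and what the synthetic benchmark does and does not
demonstrate.

## Problem setting

Smartphone photographs of acne patients are screened for usability, lesions
are detected and segmented, and each image is assigned a severity grade.
Six lesion classes are handled: comedones, papules, pustules and nodules
(compact, roughly convex — annotated and detected as axis-aligned boxes),
and cysts and scars (irregular — annotated as polygons and handled by a
segmentation branch).

## Image-quality gate (`acnekit.quality`)

The gate accepts an image when a face region is available, a sharpness
classifier scores it above `theta_sharp` (default 0.5), and an HSV
lightness test flags neither under- nor over-exposure.

*Face region.* Face detection is a callback contract
(`provider(image) -> box | None`), not a dependency: any detector can be
wired in, and an abstention is interpreted as "no usable face" (occlusion,
non-face content) and rejects the image.  Without a provider the crop falls
back to the record's known `face_region` and then to a central 80%×80%
crop, which is flagged in the report.

*Sharpness.* Six complementary blur cues are computed on the luma channel
(0.299R + 0.587G + 0.114B): variance of the Laplacian, Tenengrad (mean
squared Sobel gradient), Brenner gradient, RMS contrast against a 5×5 local
mean, Canny edge-pixel fraction, and the spectral energy fraction above
0.15 cycles/pixel.  All six are non-negative and all decrease under
Gaussian blur.  A logistic regression over the standardized features
(unpenalized maximum-likelihood fit, tolerance 1e-6, ≤500 iterations,
via scikit-learn) converts them into a sharpness probability.  The feature
set is a design choice: any six monotone blur cues would serve; these are
standard, cheap and complementary.

*Exposure.* V = max(R,G,B)/255 per pixel.  The image is `too_dark` when
mean V < `v_lo` (default 0.25) and `overexposed` when the fraction of
pixels with V > 0.98 exceeds `s_hi` (default 0.30); over-exposure takes
precedence when both trigger.  The thresholds are configuration keys;
the defaults classify all-black and all-white images correctly and pass
well-lit synthetic scenes.

## Annotation model (`acnekit.annotations`)

Coordinates are 0-based continuous pixel coordinates.  Boxes are
`(x, y, w, h)`, half-open `[x, x+w)×[y, y+h)`.  A pixel (row r, col c)
belongs to a polygon iff its center `(c+0.5, r+0.5)` is inside under the
even–odd rule; self-intersecting rings are accepted because annotators
produce them and even–odd keeps rasterization deterministic.  The JSON
dialect is COCO-like (images / annotations / categories) with `bbox` for
box classes and single-ring `segmentation` for polygon classes; writing is
canonical (sorted keys, sorted image ids), so write∘read is byte-stable.

Dataset summaries report per-class mean instances per image and percentage
shares `share_c = 100·mean_c/Σ mean_c`, rounded half-up to 2 decimals —
the convention used in clinical dataset ledgers.  `validate_splits` checks
that per-split image counts sum to the declared total.

## Center-point target codec (`acnekit.codec`)

Detection follows the anchor-free center-point scheme: with output stride
R (default 4), a box with center p maps to integer cell p̃ = ⌊p/R⌋ on a
per-class heatmap, carrying an exact 1 at p̃ and a Gaussian falloff
`exp(−d²/2σ²)` around it, combined across objects by element-wise max so
every true center keeps value 1.  The Gaussian radius r is the largest
center shift keeping IoU ≥ 0.7 with the true box (smallest root of the
three standard quadratic cases, floored at 1 cell) and σ = r/3.  This is
the convention the center-point detection lineage assumes, and both the
overlap threshold and σ rule are configuration keys.  The offset
grid stores p/R − p̃ ∈ [0,1)² and the size grid stores (w, h) in input
pixels at p̃.

Decoding takes cells that are maxima of their 3×3 neighborhood — strict
against row-major-earlier neighbors, non-strict against later ones, so
plateaus yield exactly one deterministic representative — thresholds at
`score_min`, keeps top-K (default 100), and reconstructs each box from
`R·(p̃ + offset)` and the size entries.  For scenes whose centers are ≥
2σ+3 cells apart, decode∘encode is exact to the bit, which the tests and
acceptance script verify on 100 seeded scenes.

Segmentation probabilities become instances by thresholding at 0.5,
8-connected component labeling, dropping components under `min_area` = 16
pixels, and emitting each survivor's exact outer pixel boundary (union of
pixel squares, via shapely), so rasterizing the emitted polygon reproduces
the component.

## Loss family (`acnekit.losses`)

With predicted heatmap Ŷ, offsets Ô, sizes Ŝ and segmentation maps I:

- `L_k = −(1/N) Σ [(1−Ŷ)^α log Ŷ]` at true centers (Y=1) and
  `[(1−Y)^β Ŷ^α log(1−Ŷ)]` elsewhere, with α=2, β=4.  N is the pixel
  count h·w of the down-sampled map — the default normalization here,
  chosen over the per-object normalization common in center-point
  detectors; `center_loss_norm="objects"` switches conventions.  Pixel
  normalization scales the loss by a typically larger divisor but leaves
  the optimum unchanged.
- `L_off`, `L_size`: mean L1 error over annotated center cells (both
  coordinates summed), 0 when a map contains no objects.  An L1 loss is
  non-negative by construction.
- `L_seg`: mean squared error over all M·H·W segmentation elements.
- `L_det = L_k + 0.1·L_size + 1.0·L_off`, `L_total = L_det + L_seg`,
  exact identities.

Predictions are clamped to [ε, 1−ε], ε = 1e-4, before logarithms.  Each
loss has an analytic gradient used by the trainer; the tests check all of
them against central finite differences and naive loop oracles (≤1e-9).

## Detector (`acnekit.detector`)

The network is a deliberately small aggregation CNN with the same I/O
contract as a full-scale center-point detector: a 3-level strided encoder
(stride 1 → 2 → 4; channels 16/32/48 at the default base width), upward
aggregation nodes that concatenate a shallow feature with the upsampled
deeper one and mix with a 1×1 convolution, a re-downsampled mid-level
branch fused into the stride-4 detection trunk, and four heads — class
heatmap (sigmoid), offset, size at stride 4, and a full-resolution
segmentation head (sigmoid) so the segmentation loss is averaged over
prediction-resolution pixels.  The heatmap and segmentation head biases
are initialized to logit(0.01) so an untrained model predicts the rare-
positive prior.  The backbone's scale is a design choice: the contribution
being exercised is the task composition (detect + segment + grade), not
backbone capacity, and ~70k float64 parameters train on one CPU in
minutes.  Deformable convolution, motivated at clinical scale by irregular
cyst/scar shapes, is left as a plug-in flag that this build does not
include; the desk-scale blobs do not require it.

Everything is numpy: im2col convolutions with hand-derived backward
passes, verified end-to-end against finite differences.  Training uses
Adam (lr 1e-3, β = 0.9/0.999), batch size 8, per-epoch reshuffling from a
seeded generator; a fixed seed makes runs bit-reproducible, and
checkpoints carry model weights, Adam state and the shuffling RNG state so
a resumed run matches an uninterrupted one to ≤1e-6.

## Grading (`acnekit.grading`)

Severity follows the Chinese Acne Treatment Guideline (2019) criteria —
I: comedones only; II: papules; III: pustules; IV: nodules or cysts —
combined by the maximum-severity rule: the highest grade whose defining
lesion is present.  The guideline lists criteria per grade without
stating combination logic; highest-applicable is the reading consistent
with guideline practice and with "downgrade misdiagnosis" being a
meaningful error category.  Scars never affect the grade (no grade's
criterion mentions them) but are always reported in the counts.
Lesion-free images return a NONE sentinel so the function is total.
`grade_image` counts detections with score ≥ `score_min` (default 0.3)
plus segmentation instances, then applies the rule; cysts may enter
through either path.

## Evaluation (`acnekit.evaluation`)

Detections are matched per class greedily in descending score order to the
unmatched ground truth with highest IoU ≥ 0.5 (ties to the lower index);
each ground truth matches at most once.  AP uses all-point interpolation:
Σ(R_i − R_{i−1})·max precision at recall ≥ R_i.  The error–recall curve is
1 − precision against recall at every rank.  Per-class "accuracy" in
detection reports is TP/(TP+FP+FN) — the Jaccard index of the instance
sets — an explicit definition choice, labeled as such.  Grading agreement
reports a 5×5 confusion matrix (NONE..IV), per-image accuracy, one-vs-rest
sensitivity/specificity per grade, unweighted Cohen's kappa (no weighting
variant is implied by the grading context), the downgrade fraction
(errors with predicted < reference, over errors) and the cross-grade
fraction (|pred − ref| ≥ 2, over all predictions).

## Synthetic data (`acnekit.synthetic`)

Scenes are 64×64 by default: a skin-tone background with Gaussian texture
noise (σ = 5 intensity levels), a brighter elliptical face (axes 0.40W ×
0.44H) recorded as the face region, and lesions placed uniformly inside
the ellipse with bounding-box IoU ≤ 0.3 between instances (1,000 rejected
placements raise a capacity error).  Appearance models the discriminative
cues of each class rather than photorealism: comedones are 3–5 px dark
dots; papules 5–9 px red discs; pustules 6–10 px red discs with a bright
yellowish core; nodules 11–16 px dark-red discs; cysts compact irregular
star polygons in pinkish-purple; scars elongated (2–3×) brownish blobs.
Degradations exercise the quality gate: Gaussian blur, brightness scaling,
and pushing a random pixel fraction to saturation.

Two count distributions are provided.  `clinical_mix_counts` (the
`generate_dataset` default) draws per-class Poisson counts whose means
follow the clinical validation-split mix (comedones 37%, scars 31%,
nodules 0.7%, …) scaled by 0.30 so a 64×64 face carries ≈4 lesions on
average; on 2,000 generated images the realized shares land within ±3
percentage points of that mix.  `benchmark_spec_counts` is used for the
detection benchmark and draws small uniform ranges (1–3 comedones, 1–2
papules, 0–2 pustules, 0–1 each of nodule/cyst/scar) so that every class
— including nodules, which the clinical mix would make vanishingly rare
in a 50-image test split — has enough support for per-class AP and mask
IoU to be meaningful.

## Reference benchmark (`acnekit.benchmark`)

`run_benchmark` generates 300 training and 50 test scenes (seed 7 in the
test suite), trains for 30 epochs, and reports per-class AP@IoU0.5, pooled
per-class mask IoU (Σ intersection / Σ union over all test pixels),
per-image grade accuracy and kappa against ground-truth grades.  The
problem sizes are the package's reference configuration: large enough for
stable metrics, small enough to run in minutes on one CPU.  Typical
results at these sizes: mean AP ≈ 0.85 (comedones, the 1-cell targets,
are the hardest class), cyst mask IoU ≈ 0.95, scar ≈ 0.80, grade accuracy
≈ 0.90.

## What the synthetic benchmark does and does not show

Passing it demonstrates that the encoding, losses, optimization, decoding,
segmentation extraction, grading and metrics compose into a system that
actually learns and that every contract holds end-to-end.  It does not
demonstrate clinical performance: synthetic lesions are separable by
designed color/size cues, there is no pose, illumination or skin-tone
variation, no occlusion, no annotation noise, and the class imbalance is
milder than clinical reality.  Published clinical accuracies of the
full-scale system this package models are not reproducible here and are
not claimed.

## Numerical choices and degenerate inputs

- float64 throughout the network and losses; bit-reproducibility under a
  fixed seed is tested.
- Heatmap/seg probabilities clamped to [1e-4, 1−1e-4] before logs.
- Plateau ties in decoding and equal-IoU ties in matching break toward the
  lower row-major / lower index — arbitrary but deterministic.
- Zero-object images: offset/size losses are 0; decoding an all-zero
  heatmap returns an empty list; grading returns NONE.
- AP with zero ground truth and nonzero predictions is NaN with a flag
  rather than a silent 0; per-class means skip NaN classes.
- Kappa with degenerate chance agreement (p_e = 1) returns 1 for perfect
  agreement, else 0.

## Known limitations

- The detector assumes the training input size at inference; no tiling or
  resizing is built in.
- Single-ring polygons only: a segmented component's holes are ignored
  when its outline is emitted.
- The sharpness model is only as good as its fixtures; the packaged
  features saturate (probability ≈ 0 or 1) on strongly blurred or clean
  synthetic scenes.
- No facial-region weighting of severity and no trunk imagery; grading is
  per-image from counts alone.
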