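# Methods

## Problem and pipeline

Early-stage osteonecrosis of the femoral head (ONFH) is graded clinically by
the share of the femoral head involved by the necrotic lesion, but in
practice that share is estimated visually. This package automates the
measurement on a single axial T1-weighted hip-MRI slice containing one
femoral head. Four stages run in sequence:

1. **Preprocessing.** Per-image min–max normalization to [0, 1] and a fixed
   256×256 crop (zero-padded symmetrically when the input is smaller, with
   the odd pixel going to the bottom/right). The train/test split reserves
   `round(0.8·N)` slices for training, determined entirely by a recorded
   seed.
2. **Femoral-head segmentation** with a U-Net carrying two auxiliary
   supervision paths (below).
3. **Necrosis extraction** by adaptive thresholding inside the predicted
   head region.
4. **Grading** of the pixel-level necrotic proportion, plus an overlay and a
   JSON record.

## Segmentation model

The backbone is a standard U-Net: `depth` = 4 encoder levels of two 3×3
convolutions + ReLU each, 2×2 max pooling, a bottleneck block, and a
symmetric decoder using nearest-neighbor upsampling with skip
concatenation. Channel width starts at `base_channels` = 16 and doubles per
level up to a cap of `max_channels` = 64; the cap is a desk-scale choice
that keeps single-CPU training at 256×256 in the minutes range while
leaving the architecture free to scale through the config.

Two independent auxiliary paths read the decoder features and act purely as
training constraints:

* **Geometric supervision.** A 1×1 convolution on the final decoder features
  regresses the signed Euclidean distance transform (SDT) of the true mask
  boundary, clipped to ±20 px, under an L1 loss. The SDT is zero exactly on
  boundary pixels (mask pixels with a 4-neighbor outside), negative inside,
  positive outside; an empty mask yields +20 everywhere. Distance errors
  near the boundary are penalized directly, which is the property a
  geometric constraint should add over per-pixel losses.
* **Pixel-level supervision.** Deep supervision: 1×1 convolution heads emit
  a probability map at every coarser decoder resolution, each scored by
  binary cross-entropy against block-majority-downsampled ground truth.

The composite loss is

    L = w_main · (BCE + Dice) + w_geo · MAE(SDT) + w_pix · mean_level BCE

with default weights (1.0, 0.5, 0.5). Setting `w_geo = w_pix = 0` reduces
the loss (and its gradients) exactly to a plain U-Net's BCE + Dice — the
auxiliary heads touch nothing else — which the test suite asserts to
machine precision.

Training uses Adam (lr 1e-3), batch size 4, and 12 epochs by default, with
seeded initialization and seeded shuffling so two runs with the same
configuration are bit-identical. The soft Dice loss uses a smoothing
constant of 1 in numerator and denominator so the empty-mask case is
well-defined with zero loss. Inference thresholds the probability map at
0.5, keeps the largest 4-connected component and fills holes, because each
preprocessed image contains exactly one femoral head.

### Numerical engine

The network is implemented directly on float32 NumPy arrays (channels-last)
with explicit backward passes. 3×3 convolutions use a shift-accumulate
scheme — the padded image viewed as a flat (pixels × channels) matrix, one
contiguous-slice GEMM per kernel tap — rather than an im2col column matrix;
this keeps memory traffic sequential and is what makes CPU training on
full-resolution slices practical. The convolution forward/backward passes
are verified in the tests against `scipy.signal.correlate2d` oracles in
float64, and pooling/upsampling against adjoint identities.

## Adaptive thresholding

Within the head mask, intensities are quantized to 256 bins (matching 8-bit
export; bin q ≤ t corresponds exactly to intensity < (t+1)/256). The
threshold maximizes the between-class variance ω₀ω₁(μ₀−μ₁)² over all 256
candidate splits with both classes non-empty — Otsu's criterion — with ties
broken toward the lowest maximizing threshold for determinism. Only
head-region pixels enter the histogram, so intensities outside the
segmentation can never move the threshold. Necrosis polarity is "dark"
(below threshold) by default, matching the hypointense appearance of early
necrotic marrow on T1-weighted images, and is configurable for other
sequences. An optional minimum-component cleanup exists but is off by
default. A constant head region admits no split and is reported as a
degenerate input, which the grading stage maps to proportion 0 with a
warning.

## Proportion and grading

The necrotic proportion is `100 · |necrosis ∩ head| / |head|` in percent at
pixel level. Grades follow the early-stage severity convention used with
the Steinberg system, taken literally at the interval boundaries:

| proportion p (%) | grade |
| --- | --- |
| p < 0.1 | Without ONFH |
| 0.1 ≤ p < 15 | Mild |
| 15 ≤ p ≤ 30 | Moderate |
| p > 30 | Severe |

Exactly 15 and exactly 30 are Moderate; exactly 0.1 is Mild. Grading uses
full floating precision; the JSON record rounds the proportion to two
decimals for display only. Grading is per slice; aggregation across the
slices of one hip is left to the caller.

## Synthetic phantoms

Annotated clinical MRI cannot be redistributed, so the phantom module
generates slices with known ground truth: a bright ellipse
(normalized intensity 0.8 by default) for the fatty-marrow signal of the
femoral head, a darker blob (0.3) grown in the superior portion of the head
— early lesions are typically anterosuperior — a structured background
(smoothed Gaussian random field around intensity 0.30 plus a dark
acetabular arc hugging the supero-lateral head boundary, so segmentation is
not trivially an intensity threshold), then additive Gaussian noise
(σ = 0.02) and clipping to [0, 1]. The lesion radius is found by binary
search so the rasterized necrotic share hits the requested fraction within
one percentage point whenever the head covers ≥ 2000 px; the recorded
ground-truth proportion is always recounted from the rasterized masks.
Cohorts draw head radii uniformly from 45–70 px, center jitter ±15 px,
lesion fraction 5–40 %, head intensity 0.7–0.9 and lesion intensity
0.25–0.4, with per-sample seeds derived from one master seed.

What the phantoms do **not** emulate: partial-volume blur at tissue
interfaces, bias fields and coil shading, anatomically realistic
surrounding structures (femoral neck, acetabular cartilage), or
inter-scanner intensity distributions. Passing tests therefore demonstrate
that the algorithms are implemented correctly and recover known ground
truth under controlled contrast and noise — not clinical-grade performance
on patient MRI, which requires real annotated data.

## Problem sizes and defaults

The packaged experiments train on 50 phantoms at 256×256 with 20 held-out
phantoms for evaluation and 12 epochs — sizes chosen so the full cycle runs
in a few minutes on one CPU core while still reaching held-out Dice well
above 0.9. Pixel spacing defaults to 1 mm/px, is recorded in every slice,
and is unused by any computation (all quantities are relative areas).
Evaluation pools the pixel confusion table over all test images by default;
per-image macro-averaging is available since the two differ on unbalanced
image sets, and both are exposed.

## Known limitations

* Single axial slice per judgment; no 3D context or multi-slice
  aggregation.
* The auxiliary supervision forms (SDT regression, deep supervision) are
  this package's concrete design for "geometric" and "pixel-level"
  constraints; other instantiations are possible.
* Otsu thresholding assumes a roughly bimodal head histogram; diffuse or
  very small lesions (< 0.1 % of head area are reported as Without ONFH by
  design) and non-T1 contrasts need the polarity switch or a different
  extractor.
* The NumPy training engine is single-threaded and CPU-bound; it is meant
  for desk-scale experiments, not large clinical training runs.
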