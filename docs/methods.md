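# Methods

This note documents the models, procedures and design choices behind
`ajprofiler`: what each stage computes, which parameters matter, what the
synthetic data generator does and does not emulate, and the numerical
conventions used throughout.

## The profiling model

The package summarizes the adherens-junction phenotype of an endothelial
monolayer as a **morphological profile**: a frequency vector over clusters of
cell-border appearance. The chain is

1. per-image quality control and retrospective illumination correction;
2. seeded segmentation — nuclei from the nuclear channel, then cells and
   border pixels from the junction (VE-cadherin) channel by a watershed
   flooded from the nuclei;
3. sampling of 64×64-pixel patches (ROIs) centered on border pixels;
4. a small convolutional network, trained on a 5-class border-morphology
   proxy task (linear, reticular, foci, disturbed, highly disturbed), whose
   global-average-pooling activation provides a 32-dimensional embedding of
   each patch;
5. UMAP reduction to 2D and HDBSCAN clustering, fitted once on a reference
   embedding set and frozen; new data are transformed and assigned to the
   frozen clusters;
6. per-sample cluster-occupancy frequencies (the profile), compared across
   conditions with cosine similarity, LDA + Hotelling's T², ANOVA/t-tests on
   1D reductions, and PCA.

Because global average pooling discards the position of the border inside
the patch, the embedding characterizes *what* the border looks like, not
*where* it sits — two patches showing the same morphology at different
offsets embed nearby.

## Quality control

Each image is summarized by a focus score, the total intensity sum, median,
standard deviation, and the 0.01/0.25/0.75/0.99 intensity quantiles. The
focus score is the variance of the Laplacian divided by the squared mean
intensity — a standard, illumination-robust autofocus statistic (it is not
uniquely defined by the procedure being reproduced; this choice is
config-overridable in spirit: the metric lives in one function).

Outlier thresholds are **deliberately opt-in** (`qc.thresholds` in the
pipeline config): the reference workflow relied on visual inspection of
metric histograms, and automatic robust-z cutoffs are unstable on small
image populations. When configured, a metric can carry absolute `min`/`max`
bounds and/or a two-sided `robust_z` cutoff computed as
(x − median)/(1.4826·MAD). A failed image in either channel discards the
whole site.

## Illumination correction

Per plate and channel, from ≥ 3 images:

1. **Bright-structure suppression** — pixels more than `sd_mult` (default 3)
   standard deviations above the *local median* (square window, default
   33 px) are replaced by the mean of their direct 8-neighborhood,
   iteratively (≤ 10 passes). The window and iteration cap are not
   prescribed by the source procedure; defaults were chosen so that debris
   blobs well below the window size are fully suppressed.
2. **Robust aggregation** — a "median-weighted average": a per-pixel
   weighted mean with weights inversely proportional to the absolute
   deviation from the per-pixel median. The plain per-pixel median is
   available (`aggregate="median"`); the weighted form uses all images
   while still down-weighting residual artifacts.
3. **Smoothing** — Gaussian filter (default σ = 64 px at 512-px scale;
   tests at 256 px use σ = 24). `nearest` boundary handling empirically
   gives the smallest edge bias for smoothly varying vignette fields.
4. **Correction image** — the scalar mean of the smoothed background
   divided by the smoothed background. All images of that plate/channel are
   multiplied by it.

Two properties follow from the construction and are asserted in tests: the
harmonic mean of the correction field is exactly 1, and correcting an
already-corrected stack changes it by < 1% (flatness is a fixed point).
Note the method recovers *flatness*, not the absolute unvignetted level:
corrected images sit at the image's own mean brightness, because the
absolute illumination profile is not identifiable retrospectively.

## Segmentation

All segmentation operates on quantile-normalized images: intensities are
clipped to the image's 0.01/0.99 quantiles and mapped to [0, 1] (a constant
image maps to zeros, with a warning).

**Nuclei**: Gaussian smoothing on a disc support of 5 px diameter
(implemented as radius 2 including the center — the "diameter 5" phrasing
is ambiguous between radius 2 and 2.5), Otsu binarization, morphological
opening then closing with the same disc, then a distance-transform
watershed to split touching nuclei (markers from distance-map peaks with a
10-px minimum separation). Components under 80 px² are dropped. Because
Otsu always splits a histogram — even of structure-free noise — a minimum
foreground-background contrast of 0.25 (on the normalized scale) is
required before any nuclei are accepted; a blank image yields an empty
labeling rather than spurious objects.

**Cells and borders**: the junction channel is median-filtered (same 5-px
disc), an edge-strength image is computed — the morphological gradient
(dilation − erosion, disc radius 1) by default, Sobel magnitude as an
alternative — and a watershed is flooded from the nucleus labels. Every
pixel belongs to exactly one basin (one cell per nucleus, same label). A
**border pixel** is a pixel whose 8-neighborhood contains ≥ 2 distinct cell
labels; this definition is used consistently by the generator, the
segmentation and the ROI sampler, and makes the border a ~2-px-thick ribbon
on both sides of the basin boundary. The image frame is never a border.

Coordinates are 0-based (row, col); label maps are row-major.

## ROI sampling and augmentation

Patches are sampled uniformly without replacement from the border-pixel
list, subject to a pairwise minimum spacing (default 8 px, greedy rejection
in random order) to limit near-duplicate patches, and to a margin so the
full patch fits in the frame. Sampling is deterministic given the seed.
When a dataset-level count is requested across images, per-image quotas are
assigned by ceiling division with truncation on the last images.

Training-time augmentation: independent horizontal/vertical mirror coin
flips, brightness shift δ ~ U(−0.1, 0.1) and contrast scale
γ ~ U(0.8, 1.25) applied about the patch mean, clipped to [0, 1]. The
magnitudes are not prescribed by the source protocol and are parameters of
`augment`. Patches are stored already normalized to [0, 1] so augmentation,
training and inference share one intensity scale; there is no per-patch
standardization. Rotations are intentionally absent (only mirrors,
brightness and contrast are part of the protocol).

## The CNN

A reduced Xception-style classifier implemented in numpy (`_nn.py`):
im2col convolutions backed by BLAS, depthwise-separable convolutions as
9-tap shift-multiply-accumulate passes, batch normalization, 2×2 max
pooling, and Adam. Analytic gradients are verified against central finite
differences in float64 in the test suite.

Architecture (34 k trainable parameters, well under the 500 k budget that
keeps the model "small"):

- stem: 3×3 conv stride 2 → 16 channels, 3×3 conv → 32, each with
  batch norm + ReLU;
- three residual blocks (widths 32, 64, 64): ReLU → sepconv → BN → ReLU →
  sepconv → BN → 2×2 max pool, plus a 1×1 stride-2 convolution + BN on the
  skip path;
- one separable convolution to exactly 32 channels (BN + ReLU), global
  average pooling — **this 32-vector is the embedding** — and a dense
  softmax head of 5 units. No hidden dense layer sits between the pooling
  and the classifier.

Batch normalization is part of the Xception design and is what makes the
small learning rate workable; exact block count and widths are free choices
(the reference description is only "simplified and reduced") and are
config-exposed, with tests pinning the contracts: 64×64 single-channel
input in [0, 1], 5 classes, 32-dim embedding, separable-conv residual
design.

Training: categorical cross-entropy, Adam at lr 1e-4, batch 64, up to 100
epochs by default, augmentation on training patches only, checkpoint with
the best validation loss (accuracy as tie-break) restored at the end.
Optional early stopping by patience or by a target validation accuracy;
the synthetic task is substantially easier than real imagery and converges
in ~15–25 epochs at the 500-patches-per-class scale. Training is
deterministic given the seed (pure numpy; no threading nondeterminism).

## Clustering and profiles

UMAP (2 components, n_neighbors 30, min_dist 0.0, Euclidean, fixed seed) is
fitted on a reference embedding set — target size 10,000 patches — followed
by HDBSCAN on the 2D coordinates (min_cluster_size 100 at the 10,000-point
scale, scaled proportionally with a floor of 5 for smaller fits; none of
these values are prescribed by the source). min_dist is 0 because the 2D
coordinates feed a density clusterer: a nonzero min_dist artificially
spreads points apart, which can bridge the density valley between two
adjacent morphology classes and make the clusterer merge them — with
min_dist 0 the classes that the classifier separates linearly in 32-dim
stay separable in 2D. Plots that want visual spacing can refit with a
larger min_dist; clustering always uses the packed layout. The fitted pair
is frozen in a `ReducerBundle`.

Assignment of new embeddings never refits: points are mapped through the
frozen UMAP transform and inherit the cluster label of the nearest fitted
point in the 2D plane. Two density gates route points to noise instead:
an embedding farther from the fit set (in 32-dim) than 3× the fit set's own
99th-percentile nearest-neighbor distance, or a 2D coordinate equally far
from the fit coordinates. The 32-dim gate matters because a UMAP transform
places arbitrarily remote points *somewhere* in the embedding plane; the
gate restores the "remote points are noise" semantics of density
clustering. (The clustering library used for fitting provides no
approximate-prediction for new data, so this assignment rule is the
package's own frozen-model predictor.)

A profile keeps the noise fraction as an explicit final bin rather than
silently renormalizing over clusters: profiles remain comparable across
samples with different noise rates, and assignment failures stay visible.
The observational unit is the per-well (technical replicate) profile;
condition-level comparisons pool wells.

## Statistics

- **Cosine similarity** between profiles (frequency vectors ⇒ values in
  [0, 1]); condition-level heatmaps use mean profiles.
- **LDA**: Fisher discriminant directions (eigen solver) with
  explained-variance ratios; frozen models transform new replicates without
  refitting. Singular within-class scatter falls back to a small shrinkage
  ridge, with a warning.
- **Hotelling's T²** (two-sample, pooled covariance) with the exact F
  transformation F = T²(nₐ+n_b−p−1)/(p(nₐ+n_b−2)) on (p, nₐ+n_b−p−1)
  degrees of freedom. A singular pooled covariance receives a ridge of
  1e-8·trace/p. Monte-Carlo tests confirm type-I calibration at α = 0.05
  within [0.04, 0.06] over 2000 null simulations and monotonically
  increasing power with mean separation.
- **ANOVA / t-tests** on 1D (LDA-reduced) values, with Holm step-down
  adjustment for the pairwise t-tests (the multiplicity rule is this
  package's choice). All-identical degenerate input returns p = 1 with a
  warning.
- **PCA** of profile matrices (centered, no scaling); the caller picks
  which components to plot. Profiles enter LDA/PCA as raw frequencies; a
  centered-log-ratio transform (`clr_transform`) is available but off by
  default, mirroring the reference analysis.

## Synthetic data generator

The generator is first-class, tested code: it renders what the pipeline
expects to see and returns complete ground truth, so every stage — including
CNN training — is testable without real imagery.

- **Geometry**: cells are the Voronoi tessellation of jittered grid seeds
  (cobblestone-like, controllable count); the label map is the exact
  nearest-seed rasterization, and finite ridge polylines are obtained by
  mirroring the seed set across the frame edges. Nuclei are elliptical
  Gaussian blobs at the seeds (σ 6–9 px, amplitudes 18–28 k on the 16-bit
  scale).
- **Border morphology is assigned per segment** (edge between two cells),
  drawn from the configured mixture — the unit of phenotype is the border,
  not the cell. The five renderers: *linear* = thin smooth bright line
  (σ ≈ 1 px); *reticular* = honeycomb band of small rings (radius ≈ 3 px)
  marching along the edge; *foci* = short bright fingers perpendicular to
  the edge, alternating sides (the zig-zag look); *disturbed* = fragmented
  line with ~45% gaps in ~6-px chunks; *highly disturbed* = wide dim
  diffuse band (σ ≈ 3 px). Every non-linear class keeps a faint continuous
  spine along the interface — residual junction signal at the cell-cell
  contact — which also anchors the watershed to the true edge. No
  quantitative geometry exists for these classes in real data; parameters
  were chosen once for visual plausibility and are config-exposed
  (`RenderParams`).
- **Forward optics**: multiplicative radial vignette 1 − s·(r/r_max)²,
  occasional bright debris blobs (Poisson count), additive Gaussian read
  noise (default SD 150 on the 16-bit scale) with optional Poisson-like
  shot scaling, clipped to [0, 65535] and stored as uint16.
- **Training sets** are built from single-class monolayers (degenerate
  mixtures), sampling border-centered patches whose footprint passes a
  class-purity threshold (default 0.9); balanced by construction, with an
  error naming the depleted class if an image budget cannot fill it.

What the generator does **not** emulate: photorealistic junction texture,
3D confocal point-spread functions, cell-size heterogeneity beyond grid
jitter, stimulus dose-response relationships, plate/batch/donor effects,
and staining variability. Passing tests therefore demonstrate that the
pipeline's machinery is correct and self-consistent — segmentation recovers
known geometry, the CNN learns separable border classes, clustering
recovers generative structure, statistics are calibrated — not that the
trained weights transfer to real microscope data.

## Problem sizes used in tests and the acceptance script

Segmentation recovery runs on a 25-cell 512×512 monolayer; illumination on
nine 256×256 images (vignette minimum 0.6); calibration on 2000 null
simulations; the CNN on 500 training + 100 validation patches per class
(≤ 30 epochs, early stop once validation accuracy reaches 0.93 — typical
stop ~epoch 20, held-out macro accuracy ≈ 0.97); clustering on the
1500-patch held-out set; condition profiles pool 2 sites × 200 ROIs per
replicate from 64-cell monolayers. The end-to-end pipeline fixture uses
2 conditions × 2 wells × 1 site at 256×256 with a deliberately tiny
training budget, since it checks plumbing and byte-level determinism, not
accuracy. These sizes were chosen so the whole suite runs comfortably on a
single desktop core.

## Known limitations

- The capacity ("overfit") sanity check runs at batch 8 / lr 1e-3: at the
  screening protocol's batch 64 / lr 1e-4, a 50-sample set yields one
  optimizer step per epoch, which cannot memorize anything in tens of
  epochs regardless of model capacity.
- Whether the two most similar classes (linear vs disturbed — one is
  literally a fragmented version of the other) occupy separate clusters
  depends on the trained network: for some training seeds their embedding
  clouds touch, the 2D reduction bridges them, and the clusterer merges
  them regardless of its settings. Profiles then cannot distinguish
  conditions that differ only in those two classes. The noise statistics
  and cluster-class composition of a fitted bundle should be inspected
  before trusting downstream comparisons.
- `assign_clusters` is a nearest-fit-point predictor with density gates,
  not a true HDBSCAN membership query; near cluster boundaries its labels
  can differ from what refitting would give (refitting is exactly what the
  frozen-model contract forbids).
- The UMAP transform of genuinely novel morphologies (outside the fit
  set's support) is unreliable; such patches are meant to land in the noise
  bin via the distance gates, and the noise fraction of a profile should be
  monitored as a drift indicator.
- Illumination correction assumes a smooth multiplicative field shared
  within a plate/channel; it cannot recover absolute intensity levels, and
  a 16-px frame margin is excluded from its accuracy guarantees.
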