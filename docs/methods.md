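# Methods

`nodalrad` re-implements, as a tested desk-scale pipeline, a comparison of
three radiomics feature-extraction strategies for classifying thoracic lymph
nodes on contrast-enhanced CT as PET-positive versus PET-negative:

1. **hand-crafted radiomics** — IBSI-style first-order, 3D shape, and
   gray-level co-occurrence (GLCM) features over the segmented node;
2. **deep radiomics** — spatially pooled activations of the first *k*
   stages of a frozen 2D convolutional backbone applied to a standardized
   slice stack of the node, with the depth *k* a model hyperparameter;
3. **hybrid** — first-order + shape features combined with the deep
   features (the hand-crafted texture block is dropped, since the deep
   block is its replacement).

Each feature set feeds an elastic-net (L1+L2) logistic regression and a
random forest, evaluated under patient-level repeated cross-validation with
a bootstrap bias correction for hyperparameter selection, and scored by
discrimination (AUC) and calibration-aware error (Brier score and its
scaled variant).

## Image preprocessing

Volumes are resampled to isotropic 1 mm voxels.  The image is resampled
with **mask-weighted (normalized-convolution) linear interpolation**: the
masked image and the mask indicator are resampled separately and divided,
so in-mask output voxels average only in-mask input intensities.  With a
plain linear resample, boundary voxels retained by the nearest-neighbour
mask blend in the background (−1000 HU air in the synthetic cohort), and
those partial-volume values dominate every in-mask statistic — in our
synthetic experiments a texture signal separable at AUC 0.97 in native
space disappeared entirely (AUC 0.49) after naive resampling.  Intensities
are never rescaled on the hand-crafted path.

For the deep path each node is cropped to its mask bounding box, the
out-of-mask voxels are filled with the node's mean HU, the z-axis is
linearly resampled to 10 planes (the typical node z-extent), each plane is
centered on a fixed canvas (default 64×64 px at 1 mm; planes larger than
the canvas are downscaled), and intensities are clipped to a soft-tissue
window of [−160, 240] HU then mapped to [0, 1].  Two choices here differ
from the common "stretch to CNN input size, zero background" recipe and
are config-switchable (`fill`, `xy_mode`):

* *mean fill* removes the node-versus-background silhouette, so
  convolutional features respond to tissue texture rather than to the
  segmentation outline;
* *pad instead of stretch* preserves the spatial frequency content of the
  texture across nodes of different sizes.  A stretch-resize maps each
  node's texture spectrum through a different scale factor, which for a
  frozen (untrained) filter bank buries the class signal under node-size
  variation.

## Hand-crafted features

First-order statistics use population (biased) moment estimators
(variance/SD divide by N; skewness is Fisher's g1; kurtosis is Pearson's
β2).  Texture features discretize in-mask HU with a fixed 25 HU bin width
anchored at the in-mask minimum.  The GLCM is accumulated symmetrically
over the 13 unique 3D direction offsets at distance 1 voxel, restricted to
voxel pairs that are both in-mask, and normalized to sum 1; reported
features are joint energy, joint entropy, contrast, inverse difference
moment, and correlation.  Shape features: voxel-counted volume;
surface area from a marching-cubes mesh of the binary mask lightly
smoothed with a Gaussian (σ = 0.8 voxels) — the raw 0/1 field yields a
faceted mesh that overestimates a digital ball's surface by ~9%, the
smoothed field is within ~1%; sphericity π^(1/3)(6V)^(2/3)/A; maximum 3D
diameter from the convex hull of boundary voxels; axis lengths
4·sqrt(λ) from the eigen-decomposition of the physical in-mask coordinate
covariance, with elongation sqrt(λ2/λ1) and flatness sqrt(λ3/λ1).

Voxel-based feature maps recompute a chosen first-order or GLCM feature on
the cubic neighbourhood of each in-mask voxel (intersected with the mask),
with NaN outside the mask, for spatial interpretation of what a feature
responds to.

## Deep features

The backbone is a fixed stack of stride-2 same-padded convolutions with
ReLU, default channels (32, 64, 128, 256) at full scale and (16, 32, 64,
128) in the desk-scale experiments.  Weights are frozen; nothing in the
package ever trains.  Three weight sources are supported:

* **gabor-random** (default): stage 1 is an analytic Gabor bank — 4
  orientations × log-spaced spatial frequencies (0.07–0.42 cycles/px),
  zero-DC, L2-normalized, 7×7 kernels — and deeper stages are seeded
  He-initialized random filters with their per-filter mean removed
  (zero-DC).  Trained CNN stems converge to oriented band-pass filters;
  the analytic bank provides that inductive bias without any download.
  Zero-DC matters: the pooled response of a filter with nonzero DC gain is
  dominated by the slice mean, drowning texture.
* **seeded-random**: every stage random (zero-DC), fully determined by the
  seed.
* **external-file**: all stages loaded from an `.npz` (arrays `W{i}`,
  `b{i}`), e.g. exported from a pretrained network.  Never a test
  dependency.

Each of the 10 slices is forwarded independently; stage-*k* activations
are average-pooled (arithmetic mean) over the node's spatial support on
the canvas — the support mask is carried through the stride pattern — and
averaged over slices, giving one feature per filter at depth *k*.
Restricting the average to the support keeps the node's canvas coverage
(≈ area) out of every feature.  Un-pooled stage-3 maps are exposed for
visualization; their spatial means equal the corresponding pooled features
on a single-slice stack, which is tested.

## Synthetic cohort

No real data ship with the package; the generator emulates the study-scale
conditions: ~100 patients; node counts per patient from a rounded normal
(mean 27, SD 14) truncated at 1; overall PET-positive prevalence 0.203
realized through per-patient positivity rates drawn from a beta
distribution with mean 0.203 and SD 0.25 (matching the reported
patient-level dispersion), so positives cluster within patients; native
anisotropic voxel spacing (0.7, 0.7, 2.0) mm; ellipsoidal nodes (base
radius 5 mm, SD 1.2 mm, 12% per-axis jitter) on an air background
(−1000 HU); in-node intensities around 45 HU (SD 12) with 15 HU white
acquisition noise and a 25 HU-amplitude correlated texture field.

Three independent class-signal channels, each zero-able:

* **size** (`size_effect`, default 2 mm): added to the positive-node mean
  radius — visible to shape features;
* **attenuation** (`attenuation_effect`, default 15 HU): added to the
  positive-node mean HU — visible to first-order features;
* **texture** (`texture_effect`, default 0.8): positive nodes carry
  *directionally organized* (streaky) internal texture — an elongated
  smoothing kernel along a fixed in-plane axis.  The transverse
  correlation scale is solved numerically so that the direction-summed
  distance-1 field correlation matches the isotropic negative-class
  texture: a co-occurrence matrix pooled over all 13 directions then sees,
  to first order, no class difference, while orientation-selective filters
  see the streaks clearly.  The texture field is variance-normalized, and
  the per-class amplitudes are additionally calibrated so the
  post-resampling texture variance is equal across classes (linear
  interpolation attenuates short-correlation fields more) — keeping the
  channel invisible to per-voxel histogram statistics end to end.

This construction deliberately separates what the three feature families
can capture: shape sees size, first-order sees attenuation, and the
texture channel discriminates *between* texture estimators — a
direction-pooled GLCM retains only a residual signal while the oriented
deep features capture it strongly.  That is the mechanism by which the
hybrid feature set (first-order + shape + deep) can beat both the
hand-crafted set (whose GLCM block is texture-weaker) and the deep set
alone (which is blind to size and attenuation by construction: zero-DC
filters and mean fill remove absolute level and silhouette).  What passing
the synthetic experiments does **not** show: that these margins transfer
to real CT, where texture is not Gaussian, segmentations are imperfect,
and a trained backbone sees far richer structure.

Known leakage limits of the generator (measured, not hidden): extreme
order statistics (minimum/maximum/range) and the discretized entropy
retain a small dependence on correlation structure even after variance
calibration; on the standard cohort the best single first-order feature
stays within ~0.1 AUC of chance while the deep block exceeds 0.9.

## Models and evaluation

Features are standardized (train statistics only) and optionally
decorrelated with PCA retaining the smallest component count explaining
95% of variance (`use_pca` is itself a searched hyperparameter).  The
elastic-net logistic regression uses the saga solver (tol 1e-5, max 1000
epochs — tighter settings change probabilities far below metric
resolution but cost seconds per fit) followed by a Newton polish of the
unpenalized intercept, which is a no-op at a converged optimum but fixes
the calibration of strongly-shrunk fits where saga stalls after one
epoch.  The random forest uses no class weighting, like every model here,
so predicted probabilities keep their natural calibration.

Cross-validation is 20-fold, 10-times repeated (desk-scale runs use fewer
folds/repeats; sizes are stated with each experiment), with splits at the
patient level.  Partitions are drawn by a randomized greedy assignment
that equalizes per-fold positive-node counts and node counts
("prevalence-residual balancing").  Besides guaranteeing two-class
training sets, this suppresses a pessimistic artifact of pooled
out-of-fold AUC: near-intercept models predict their fold's training
prevalence, which anti-correlates with the fold's test prevalence under
patient-clustered positivity, driving pooled AUC of uninformative
configurations well below 0.5.

Per repeat, out-of-fold predictions are pooled into one prediction per
node per hyperparameter configuration; metrics are computed per repeat
and averaged.  The naive reference for the scaled Brier score predicts
each node's fold-training prevalence (the uninformative model under the
same CV).  Because selecting the best configuration on pooled predictions
is optimistic, the bootstrap bias correction (BBC) draws nodes with
replacement, selects the winner on the draw (by Brier score, the primary
metric), and scores it on the out-of-bootstrap nodes only; the corrected
estimate is the mean over draws (default B = 1000) and CIs are percentile
intervals of the same distribution.  The operating point (sensitivity,
specificity) comes from an exhaustive Youden-index scan over probability
midpoints, ties resolved to the smallest cutoff.  Calibration curves are
lowess fits (fraction 0.6, 50-point grid, no robustness iterations —
robust reweighting treats minority-class outcomes as outliers and biases
the curve) of outcome on predicted probability.  Arms are compared with a
paired bootstrap z-test on AUC and Brier differences; no multiple-testing
correction is applied.

## Degenerate inputs and numerical conventions

0-based voxel indices; inclusive bounding boxes; spacing in mm.  Empty
masks raise; single-voxel masks get box surface area and zero axis
lengths with elongation/flatness defined as 1; constant regions give GLCM
correlation 1, joint energy 1, entropy 0; constant predictions give a
single-point calibration curve; a paired test with identical predictions
reports p = 1; zero bootstrap variance with nonzero mean reports the
machine-floor p and a flag.  All randomness flows from explicit seeds
through `numpy` `SeedSequence` spawning, so every experiment is bit-for-bit
reproducible from its config and one global seed, independent of execution
order.

## Problem sizes of the packaged experiments

The validation experiments are sized for a single CPU: the null-signal
BBC experiment uses 30 patients (~600 nodes, all effects zero, mild
patient clustering), 50 random configurations, 10 folds, one repeat and
B = 500; the standard-cohort comparison uses 60 patients (~1600 nodes),
6 configurations per model family shared across the three feature sets,
10 folds, one repeat, depth choices {1, 2}, and B = 300; the backbone is
(16, 32, 64, 128) channels on a 64×64 canvas.  The full-scale defaults
(100 patients, 10×20-fold CV, B = 1000, 224×224) are available through the
same configs.
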