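# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `stromaprog`, in the order the pipeline runs.

## Tile geometry and the overlapping-tile strategy

Slides are plain rasters at a stated resolution (default 0.25 μm/px; no
pyramidal WSI decoding).  The ROI polygon is rasterized with an even-odd
(crossing-number) fill evaluated at pixel centres — deterministic and easy
to check against an independent point-in-polygon oracle.  Output windows
(212 px) form a regular grid of stride 212 anchored at the ROI bounding
box; a window is kept iff it contains an ROI pixel, so the kept windows
partition the ROI.  Input windows are the output windows dilated by the
margin (396 − 212)/2 = 92 px; pixels beyond the slide edge are filled by
symmetric mirror reflection (the border row/column participates in the
mirror once).  Tiles whose output window only partly intersects the ROI
are kept and the out-of-ROI pixels are masked after stitching — this keeps
area accounting exact.  Coordinates are 0-based with half-open windows.

## Stain normalization (Macenko)

RGB is converted to optical density (OD = −log10(I/255), intensities
floored at 1 to avoid infinities).  Near-transparent pixels — all channels
below the OD floor β = 0.15 — are discarded; if fewer than 100 pixels
remain the tile is declared blank and the caller falls back to the
reference profile.  The two leading eigenvectors of the OD scatter span
the stain plane; the directions at the α and 100−α percentile angles
(α = 1 by default) are the stain vectors, ordered so the first column is
the hematoxylin-like vector (stronger red absorption), sign-fixed
non-negative and unit-normalized.  Per-pixel stain concentrations come
from non-negative least squares, solved in closed form for the
two-variable case (unconstrained solution when feasible, otherwise the
better single-stain fit) — vectorized over pixels.  Robust maxima are the
99th concentration percentiles.  Normalization rescales concentrations by
the ratio of reference to source maxima and re-composites with the
reference stain matrix.  For tiles whose OD lies in the source stain
plane this is an identity when source == reference; pixels outside the
estimated angle wedge are clamped, which is the usual behaviour of the
method.  The default reference profile is estimated once from a fixed
synthetic scene.

## The valid-convolution U-Net

Topology: `depth` = 4 encoder levels of {two unpadded 3×3 convolutions +
ReLU + channel-wise dropout (rate 0.10), 2×2 max-pool}, a two-convolution
bottleneck, and 4 decoder levels of {2× stride-2 transpose convolution,
centre-crop-and-concatenate skip, two unpadded convolutions}, closed by a
1×1 convolution and softmax over 3 classes.  The geometry calculator
traces every intermediate size and raises a named error if a size becomes
non-positive, odd before pooling, or un-croppable at a skip; for input
396 it yields 212, and for the classic 572 input it yields 388.

The implementation is plain numpy (float32): im2col + BLAS GEMM
convolutions with explicit backward passes, verified against central
finite differences.  No deep-learning framework is required.

Training: pixel-wise categorical cross-entropy over non-ignored pixels
(the 255 sentinel marks out-of-ROI), optional per-class weights
(unweighted by default; inverse-frequency weights are what the test suite
uses to counter the ~1% lymphocyte share), Adam (default lr 1e-3),
gradient accumulation in micro-batches so large nominal batch sizes fit
in memory.  The reference schedule is the one the pipeline was designed
around: batch size 160, up to 50 epochs, learning rate ×0.1 after 3
monitoring intervals without improvement, early stop after 5.  A
"monitoring interval" is one epoch of the mean training loss; the
schedule object is pure and unit-tested on synthetic loss sequences.
Weight initialization, shuffling and dropout are all driven by explicit
seeds; eval-mode inference is deterministic.

Evaluation pools confusion counts across tiles: per-class IoU and Dice,
categorical accuracy over non-ignored pixels; classes absent from both
prediction and truth are excluded from means (NaN per class).

## Quantification

Class areas are integer pixel counts inside the ROI; the stromal area is
defined by subtraction, `A_Stroma = A_ROI − (A_Tumor + A_Lymphocytes)`,
and fractions divide by `A_ROI`.  TIP is computed as `1 − (SIP + LIP)` so
the three fractions sum to 1.0 exactly in floating point (TIP equals
`A_Tumor/A_ROI` to within one ulp).  LIP counts every lymphocyte pixel in
the ROI, not only stromal lymphocytes.  Patients with several slides are
aggregated by pooling pixel counts, i.e. an ROI-area-weighted mean of the
fractions.  Absolute calibrated areas are not produced; prognosis uses
fractions.

## Cutpoint searches

Candidate thresholds sit at midpoints between consecutive distinct marker
values, making both searches invariant under strictly increasing marker
transforms.  Both enforce a minimum group share of 10% of the cohort
(neither the X-tile tool nor the method family fixes a canonical minimum;
10% is this package's default).

*Binary (maximally selected rank statistic).*  For each admissible cut
the standardized log-rank statistic |Z| = |U|/√V is computed from prefix
at-risk/event matrices over marker rank, so the whole scan is two matrix
products; the maximizing cut is returned, ties broken toward the smaller
threshold.  The p-value uses the Lausen–Schumacher (1992) improved
Bonferroni approximation over the scanned quantile band; a seeded
permutation p-value (recommended ≥1000 permutations) is available as an
option and is cross-checked against the approximation in the tests.

*Two-cut (X-tile style).*  All ordered pairs (c1 < c2) with admissible
group sizes are scored by the 3-group log-rank χ² (2 df).  The statistic
factorizes over rank prefix sums: the score vector is a difference of a
1-D prefix array and the covariance entries come from one Gram matrix, so
the exhaustive scan over ~10⁵ pairs is three matrix products plus a
vectorized 2×2 solve.  The maximized χ² is reported *descriptively*,
without a selection correction (its naive 2-df tail probability is
selection-biased and is labelled as such); ties break to the
lexicographically smallest pair.  Both searches are tested for exact
agreement with brute-force double-loop oracles.

## Survival analysis

Deaths within 30 days of surgery are excluded (`os_days ≤ 30` when a day
column exists, otherwise `os_months < 1`); censored records of any length
are kept.  Kaplan–Meier estimation, log-rank tests and Cox fits delegate
to lifelines (Efron tie handling; log(−log) confidence bands).  The
median OS is the earliest time at which the survival estimate falls to
0.5 or below, "not reached" (inf) when it never does.  The Cox screen
fits one model per variable, carries every variable with p < 0.05 into a
single joint model (no stepwise refinement), and flags joint p < 0.05
variables as independent predictors; collinear selections raise rather
than being silently regularized.  Baseline tables use Mann–Whitney
(continuous, two groups), Kruskal–Wallis (more), χ² (unordered
categorical) and the (n−1)·r² linear-by-linear trend statistic (ordered
categorical).  All p-values are two-sided with α = 0.05.

## Synthetic data: what it emulates and what it does not

Scenes are procedural, not generative: tumor glands are perturbed-circle
polygons (with a paler lumen) rasterized by the same even-odd rule as the
ROI, lymphocytes are clusters of small discs evaluated exactly at pixel
centres, stroma is the textured background.  The mask *is* the painted
geometry, so ground truth is pixel-exact.  Appearance is composed in OD
space from two fixed H&E stain vectors via Beer–Lambert, with anisotropic
fiber texture in the eosin channel, fine concentration grain, and an
optional per-channel log-normal stain jitter emulating scanner/staining
variation.  Not emulated: realistic nuclear morphology, scanner
artifacts, pen marks, tissue folds, out-of-focus regions, or the
morphological ambiguity between normal and malignant glands that makes
the real task hard.  Passing segmentation tests therefore demonstrates
that the pipeline's geometry, training loop and evaluation are correct —
not that the network would reach the same accuracy on clinical slides.

Cohorts: SIP ~ Uniform(0.20, 0.95) and LIP ~ Beta(2, 80) (median ≈ 0.02,
matching the observed scale of lymphocyte fractions); true SIP cuts
(0.54, 0.75) and LIP cut 0.02 define four latent groups with exponential
event rates per month — 0.015 (intermediate ∧ LIP-high), 0.029 (either
favourable), 0.058 (neither) — chosen to give group medians of roughly
46/24/12 months, the U-shaped stroma effect and a protective LIP effect.
Censoring is independent exponential (0.005/month) plus administrative
cutoff at 120 months; the generating process says nothing about the
censoring of real cohorts.  Everything is a pure function of the seed.

## Problem sizes used by the test suite

The suite favours sizes that exercise every code path while remaining
desk-scale: oracle-equivalence checks use 50 random cohorts of n ≤ 100
(the double-loop two-cut oracle on the n ≤ 60 subset); cutpoint recovery
uses 50 seeds at n = 500 (binary) and 20 seeds at n = 600 (two-cut);
hazard-ratio recovery uses n = 2000; the segmentation check trains a
narrow U-Net (base width 6) for up to 10 epochs on 200 normalized 396-px
scenes with inverse-frequency class weights and evaluates per-class Dice
on 40 held-out scenes.  The scenes carry six lymphocyte clusters
(≈1.5% lymphocyte pixel share) so the class is represented stably in
every tile — the balanced-training-set composition the method calls for;
at ~1% share the per-tile 99th-percentile stain concentration becomes
bimodal and normalization flickers between two color regimes.  With
those sizes the trained network reaches per-class Dice ≈ 0.99/0.98/0.82
(stroma/tumor/lymphocyte).

## Known limitations

* The network is CPU-oriented and narrow by default; it is not intended
  to reproduce clinical-cohort accuracies, which require the original
  slides and GPU-scale training.
* The two-cut search reports a selection-biased χ²; use it for ranking
  divisions, not as a calibrated test.
* The Lausen–Schumacher p-value is an asymptotic approximation; for
  small cohorts prefer the permutation option.
* Stain normalization clamps pixels outside the estimated stain wedge;
  heavily artefactual tiles should be filtered upstream.
* Multi-slide aggregation assumes slides of a patient are exchangeable;
  no within-patient heterogeneity model is fitted.
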