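# Methods

This note records the models, parameter choices and numerical decisions
behind `oralfuse`, and what the synthetic benchmarks do and do not show.

## Problem setting

The package targets binary classification of histology-style RGB images
(healthy tissue vs. oral squamous cell carcinoma) through fused feature
vectors: handcrafted texture descriptors, deep-network feature vectors, a
metaheuristic feature-selection step, serial concatenation of the selected
blocks and a multi-classifier evaluation with exact confusion-matrix
metrics. OSCC is the positive class throughout.

## Synthetic data

Real H&E slides are deliberately out of scope; all executable benchmarks
run on two seeded generators.

**Texture images.** Dark elliptical blobs (nuclei proxies, hematoxylin-like
purple, per-blob colour jitter sd 12) on a noisy pink background
(eosin-like base, Gaussian noise sd 8 per channel). Class contrast enters
through blob density — Poisson means 10 (healthy) vs 40 (OSCC) per image,
emulating the higher nuclear density of carcinoma tissue — and blob size
(radius uniform on 3–7 px, scaled ×1.3 for OSCC). Default side 224 px.
Per-image seeds derive from (config seed, image index, class), so a dataset
is reproducible and extending it preserves existing images. The generator
makes no attempt at realistic H&E rendering, stain variation, tissue
architecture or imaging artifacts; consequently the texture classes are far
easier to separate than real slides, and near-100% accuracies on this
benchmark certify plumbing and discriminative direction, not clinical
performance.

**Feature tables.** Gaussian noise (sd σ = 1 by default) over n columns, of
which a recorded subset is informative: class means sit at ∓δσ/2, so the
class-mean difference is exactly δσ. The recorded indices are the ground
truth for selection-recovery scoring. Columns are independent; correlated
feature structure (ubiquitous in real deep features) is not modelled, which
makes exact-recovery claims cleaner but optimistic.

## Handcrafted block (416 values)

* **Grayscale**: ITU-R 601 luma (0.299 R + 0.587 G + 0.114 B), applied once
  at module entry.
* **Weighted LBP** (4 × 59 = 236): intensities are rescaled as
  clip(W·I, 0, 255), quantised to 8 bits, then standard uniform LBP with 8
  neighbours at radius 1 (scikit-image `nri_uniform`: 58 uniform patterns +
  1 catch-all). Rescaling saturates progressively with W, giving four
  contrast regimes of the same texture. The weighting rule is a strategy
  hook; an alternative (e.g. radius = W) can be swapped in per call.
  Histograms are normalised to frequencies (image-size independent) and
  binned over interior pixels only, so border artifacts never enter; a flat
  image therefore puts all mass in the single flat-pattern bin. LBP codes
  are offset-invariant up to clip saturation.
* **DWT subband descriptors** (4 × 45 = 180): one-level 2-D Haar transform
  with periodization boundary handling (orthonormal, so subband energy
  equals input energy exactly — tested as such). Each subband, in the order
  approximate/vertical/horizontal/diagonal, is partitioned into a 9×5 block
  grid (`array_split`, so uneven sizes are tolerated down to 9×5 subbands)
  and summarised by the mean absolute coefficient per block, row-major.
  The 45-value summary is this package's choice of a deterministic,
  resolution-independent subband descriptor of exactly the contracted
  length.

## Deep-feature stage

An extractor is a pure function image → 1000 values (the final 1000-way
output of the classic ImageNet classifiers). The deterministic mock
extractor computes 102 image statistics (8×8 grid means, 4×4 gradient-energy
blocks, 16 intensity-histogram bins, per-channel means/sds) and pushes them
through a fixed seeded Gaussian projection with tanh squashing. It is
deterministic given (seed, image bytes), separates the synthetic classes
(held-out two-sample test p ≪ 0.01 at 100 images/class) and stands in for
pretrained networks everywhere in the tests and pipeline. Torchvision
adapters (vgg16/19, resnet18/50/101, densenet201, stock weights, ImageNet
preprocessing) are declared behind an optional extra and import lazily;
they are not exercised by the core suite.

## Artificial Hummingbird Algorithm

Maximizer over a finite box [L, U]^d, n_birds = 25 and max_iter = 2500 by
default (the published configuration for the selection task; callers pass
smaller budgets where appropriate).

* **Moves.** Guided: V = X_tar + a·D⊙(X_i − X_tar); territorial:
  V = X_i + b·D⊙X_i; a, b ~ N(0,1). Direction masks D are axial (one
  coordinate), diagonal (random subset of 2…d−1 coordinates) or
  omnidirectional (all), drawn uniformly by default and configurable; for
  d < 3 diagonal collapses to omnidirectional.
* **Schedule.** Guided vs territorial with probability 1/2 per bird per
  iteration; migration every 2·n_birds iterations re-seeds the worst source
  uniformly and clears its visit counters. In a migration iteration the
  worst bird's move *is* the migration, so the evaluation budget is exactly
  (max_iter + 1)·n_birds.
* **Visit table.** After a forage, the bird's counters toward all other
  sources increment and the counter toward its guided target resets; the
  target is the source with the maximal counter, ties broken by higher
  fitness then lower index. The diagonal is never read.
* **Acceptance.** Strictly worse candidates are rejected; equal-or-better
  candidates are accepted. Accepting ties matters: rank-based selection
  fitness is piecewise constant, and rejecting equal-fitness moves freezes
  all sub-threshold coordinate drift, trapping the swarm in local optima of
  the single-swap neighbourhood (observed as recovery plateaus invariant to
  budget). For continuous objectives ties are measure-zero and behaviour is
  unchanged. The best-so-far trace is monotone either way.
* **Bounds.** Candidates clamp to the box with a vanishing random inset
  (≤ 10⁻⁶ of the span): a hard clamp piles coordinates onto exactly the
  boundary value, and rank-based binarization cannot swap through such tie
  clusters.

## Feature selection

The wrapper searches [1, 2]^d (ranking is shift-invariant; the lower bound
sits away from 0 because the multiplicative territorial move has an
absorbing fixed point there), binarises a position by keeping its k largest
coordinates — the published retained counts (371/416/103/366) are exact, so
a thresholded mask would not do — and scores a mask by the Euclidean
distance between the two class centroids on per-column standardized
features (zero-variance columns standardize to 0; the empty mask scores 0
by convention). k is a user input; how the canonical counts were originally
chosen is not derivable, so they are defaults, not constraints. At δ = 2
(n = 400, d = 100, 10 informative, 300 iterations) the wrapper recovers
≥ 8/10 planted columns in 10/10 probe seeds; at δ = 10 with the full
2500-iteration budget recovery is exact in 9–10 of 10 seeds.

## Fusion and ensembling

Serial concatenation joins named blocks in the requested order and records
(name, start, length) boundaries; with the canonical counts this gives
787 = 371 + 416, 890 = 787 + 103 and 469 = 366 + 103.

Ensemble weights are w = Σ tanh(m/100) over the five metrics of a model.
Metrics enter as fractions: on the raw percent scale tanh saturates to ~1
for any realistic metric and all models would weigh the same (5·tanh(1) ≈
3.808 is the perfect-model weight under the fraction convention). Two
ensemble readings are provided, since the feature-level and
probability-level interpretations are both defensible: `build_edf`
(element-wise weighted mean of equal-length deep vectors, then AHA
reduction — feeds the ensemble+handcrafted recipe) and
`ensemble_probability`/`ensemble_predict` (weighted average of class
probabilities, argmax with ties to the lower class index).

## Classification bench

softmax = multinomial logistic regression (lbfgs; an SGD variant is a
parameter away), decision tree (unlimited depth), random forest (100
trees), KNN (k = 5 — unspecified upstream, so a standard default), linear
SVM. Features are standardized with train-fold statistics for the
distance/margin models; trees see raw features. The "80/10/10 with 3-fold
cross-validation" scheme is internally ambiguous; it is implemented as
three repetitions with rotated, disjoint stratified 10% test partitions
(each class split into ten seeded chunks; fold f tests on chunk f,
validates on chunk f+3). Best fold = maximal test accuracy, reported
alongside mean ± sd. Reports always recompute from the stored confusion
matrix, so tables and matrices cannot drift apart.

## Metrics

AC, MC = 100 − AC, PR, SE, SP, F1 from TP/FN/TN/FP, percent scale, rounded
half-away-from-zero to 4 decimals in exact rational arithmetic (`Fraction`),
so reproduction of published tables is bit-exact rather than
float-approximate. Zero-denominator metrics are flagged undefined, never
silently 0 or 100. The shipped regression fixture contains 72 published
confusion-matrix rows; the engine reproduces every defined cell to 4
decimals, except one misclassification cell that contradicts its own
accuracy (MC printed as 1.0000 where AC = 100) and is flagged as a typo in
the fixture. ROC curves and trapezoid AUC come from scikit-learn and are
cross-checked in the tests against a brute-force concordant-pair count;
constant scores yield the chance diagonal (AUC 0.5) with a warning.

## Pipeline

One config, one seed: the seed fans out via `SeedSequence` into per-stage
seeds (image generation, extractors, selection runs, splits). Recipes map
directly to the feature families (single-deep, dual-deep, ensemble-deep,
each optionally + handcrafted); the fused dimension implied by the
configured ks is checked before any classifier trains. Deep extraction is
cached in-process by (extractor, image-set content hash). Reports are
JSON-stable modulo timings.

## Problem sizes used in the checks

The executable benchmarks are scaled for a desk machine as the package's
own test design: selection recovery uses 400×100 tables over 10 seeds; the
end-to-end benchmark uses 200 images per class (one tenth of the published
3000-image study) over 5 seeds with 150-iteration selection runs; the
dimension-identity checks use 12 images per class at 96 px, where all
dimension arithmetic is size-independent.

## Known limitations

* The synthetic texture benchmark saturates: the handcrafted block alone
  classifies blob textures essentially perfectly (blob density and size are
  precisely what LBP histograms and wavelet energies measure), so fusion
  benefits appear against the deep blocks, not against the handcrafted
  block; on real slides the roles are typically reversed.
* The weighted-LBP rescaling rule and the 45-value subband summary are this
  package's explicit choices of under-determined descriptor details; both
  are hooks, and alternative choices change feature values (never the
  dimension contracts).
* The optimizer is sequential; determinism per seed is guaranteed, parallel
  evaluation is not attempted.
* Mock deep features are linear projections of image statistics; they
  cannot emulate the representational structure of real CNN features, only
  their dimensionality and class separability.
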