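# Methods

This note documents the models, the training procedure, the synthetic study
conditions, and the numerical and design choices made where the method left
room for interpretation.

## Data model and preprocessing

Input is one numeric matrix per omics type (samples × features) plus a
clinical table of survival time in days and an event indicator (1 = death,
0 = censored).  Preprocessing applies, in this order: removal of features
that are missing *or exactly zero* in more than 20% of samples; removal of
samples with more than 20% bad features (the order matters and is asserted
by a test); KNN imputation in which the neighbours are *features* (nan-aware
Euclidean distance over mutually observed samples, k = 10 by default, the
behaviour of the gene-wise KNN imputation conventional for omics matrices);
restriction to samples present in all three omics types and the clinical
table; and concatenation into one vector per patient in the block order
mRNA | miRNA | methylation.  Survival times pass through unscaled — only
their ordering and the event flags enter any computation.

Model-facing scaling depends on the architecture: the baseline variant
consumes row-wise unit-norm-scaled vectors; the custom variant consumes
per-feature min-max-scaled values in [0, 1] (constant features map to 0).
Both scalings are idempotent.

## Architectures

Both variants are symmetric feed-forward autoencoders around a 100-unit
bottleneck, implemented directly in numpy with hand-written
backpropagation (gradients are verified against finite differences in the
test suite):

| | baseline | custom |
|---|---|---|
| hidden widths | 500 / 100 / 500 | 1000 / 100 / 1000 |
| activation (all layers) | tanh | sigmoid |
| dropout | 0.5 on the wide hidden layers | none |
| L1 kernel penalty | 1e-3 | 1e-3 |
| L2 activity penalty (output) | 1e-4 | none |
| optimiser | SGD, lr 0.01, batch 1 | Adam, lr 1e-3, full batch |
| epochs | 10 | 40 |
| survival branch | no | when the loss uses L_S |

The loss → architecture pairing is fixed: BCE and MSE train the baseline
variant; L_RC, L_RS and L_RSC train the custom variant.  The survival
branch is a single linear unit on the bottleneck (no bias, no activation)
so its output is literally `W′φ(x)`.  Learning rates and initialisation are
not intrinsic to the method and are exposed in the architecture spec;
defaults are Glorot-uniform weights, zero biases, and the Keras-default
optimiser settings.  The survival branch starts at **zero** — the null Cox
model — so the risk direction grows along the score gradient rather than
along an arbitrary random projection; with random branch init the survival
term begins by amplifying noise and the learned subgroups degrade markedly
on synthetic cohorts.

Dropout is applied to the two wide hidden layers only, never to the
bottleneck (masking the representation layer itself would destroy the very
features being learned) and only in training mode; encoding is always
deterministic.

## Loss terms

* **Reconstruction** `L_R = (1/n) Σ ‖x_i − x̂_i‖²` averages the *per-sample
  squared norm* over samples.  This differs from the element-mean MSE of
  common frameworks by a factor of the feature count; the α/β/γ weights are
  calibrated against this convention, so it is implemented exactly so.
* **Binary cross-entropy** is the element mean of
  `−[x log x̂ + (1−x) log(1−x̂)]` with x̂ clipped to [1e-7, 1−1e-7] (the
  baseline's tanh output can leave (0, 1); the clip also zeroes the gradient
  there).  Targets must lie in [0, 1], which unit-norm scaling of
  non-negative omics data guarantees.
* **Clustering** `L_C = (1/n){Σ‖b_i − μ_i‖² − Σ‖b_i − λ_i‖²}` uses the
  nearest (μ) and second-nearest (λ) centroid per sample; with k = 2, λ is
  simply the other centroid.  The term can be negative; it falls as
  clusters tighten and separate.  Centroids are constants within an epoch.
* **Survival** `L_S` is the negative Breslow partial log-likelihood of the
  branch scores.  As a standalone function it is unnormalised, exactly as
  the partial likelihood is written (all-censored cohorts give 0; a single
  event gives 0; two untied events with equal scores give ln 2; adding a
  constant to all scores changes nothing).  Inside the training loop the
  term (and its gradient) is **averaged over the batch**, the standard
  reduction of the deep-learning stacks this family of models is built on.
  Without that reduction the survival gradient scales with the number of
  events and overwhelms the per-sample-mean reconstruction term: on
  synthetic cohorts the representation then degenerates by epoch 40 into a
  one-dimensional encoding of the *observed* event ranking — log-rank
  P-values become astronomically small and the group split very uneven,
  while agreement with the planted subgroups collapses.  The batch-mean
  convention keeps the α/β balance independent of cohort size and lets the
  survival supervision act on the genuine risk structure.
* Ties in observed time share risk sets (Breslow); the Efron correction is
  out of scope.  The log-sum-exp is max-shifted, so scores beyond ±700 do
  not overflow.

## Training loop

When L_C is active: one epoch of reconstruction-only warm-up (parameters
kept), bottleneck inference, centroid seeding at the two bottleneck vectors
with the largest pairwise Euclidean distance (ties resolve to the
lexicographically smallest index pair), nearest-centroid assignment; after
every subsequent epoch, centroids are reset to their group means and samples
reassigned (standard k-means monotonicity holds for a frozen encoder, and is
asserted).  A group that empties is re-seeded with the sample farthest from
its nearest surviving centroid, keeping k constant.  When L_S is active,
samples are sorted once by descending observed time and never shuffled; the
prefix structure of that order yields the risk sets.  Full-batch training
takes exactly one gradient step per epoch.

The per-epoch trace records each loss term, the regularisation penalties
and — when centroids exist — the silhouette of the current assignments on
the current bottleneck, preceded by an epoch-0 entry giving the silhouette
of the seeded assignments themselves, which is the curve's natural starting
point.

## Subgroup labelling and evaluation

BCE/MSE bottlenecks are first screened by univariate Cox models (score-test
P < 0.05) and the survivors clustered by k-means (kmeans++, ten seeded
restarts) with k ∈ 2..5 chosen by the mean silhouette (ties → smallest k).
L_RS clusters all 100 bottleneck features the same way; the description of
the method fixes k-selection only for the baseline, so the same
silhouette-based rule is applied.  L_RC/L_RSC take nearest-centroid labels
from the final training centroids (ties to the lower index; an empty
evaluation-time cluster is kept with a warning).  Subgroup survival
separation is the pairwise two-sided log-rank test (raw P-values, no
multiplicity correction by default); curves come from the Kaplan–Meier
product-limit estimator.  Singleton clusters contribute 0 to the silhouette;
the all-singletons case is defined as 0.

The univariate Cox fit maximises the Breslow partial likelihood by Newton's
method with steps capped at ±1 and at most 50 iterations; P-values come
from the score test at β = 0 (identical to the log-rank test for binary
covariates).  Near-separated covariates — which real bottlenecks produce —
are flagged as non-converged instead of reporting unbounded hazard ratios.
Zero-variance covariates return a non-converged fit with P = 1.

## Feature discovery

On the preprocessed (pre-model-scaling) matrix: median-norm scaling
(per-feature division by the feature median, ε-guarded; a per-sample variant
is available by configuration since the term admits both readings), then
robust scaling (median/IQR) for mRNA and methylation and row-wise unit-norm
for miRNA; one-way ANOVA per feature against the cluster labels (constant
features get F = 0, P = 1 so ranking stays total; for two groups F equals
the squared two-sample t statistic, asserted in tests); per omics type the
floor(10%) smallest-P features are kept if P < 0.005 — the Bonferroni
threshold 0.05/number-of-runs, recomputed when the run count differs from
ten.  Across seeded runs, features are counted at the 60%/80%/100%
frequency thresholds (6/8/10 of ten); "robust" means present in every run,
and a loss's "novel" features are its robust set minus the union of the
other losses' robust sets.  Z-score matrices for heatmaps are clipped to
±3 with samples ordered by cluster.

## Pipeline protocol

Each loss runs over several seeds (ten by default; the run seed drives
parameter initialisation and k-means restarts, never the data).  The best
run per loss is the one with the smallest pairwise log-rank P, ties broken
by silhouette — the same selection rule the comparison report uses.  Run
summaries contain no timestamps, so identical configuration and seeds give
byte-identical JSON.

## Synthetic study conditions

The generator plants k subgroups (balanced, permuted) that shift a disjoint
set of informative features per omics block by `effect_size` noise SDs
(cluster c is shifted by c × effect_size) on a positive baseline level of 6
with unit noise SD — emulating non-negative expression/methylation
summaries so unit-norm scaling lands in [0, 1].  Event times are exponential
with rate `baseline_hazard × hazard_ratio[cluster]`; censoring is an
independent exponential clock, so the censored fraction has the closed form
c/(c+e) per cluster (asserted).  Defaults: 120 samples, blocks 300/30/300
with 20/3/20 informative features, effect size 3, baseline hazard 1e-3/day
(median survival ≈ 693 days, a realistic scale for an aggressive cancer
cohort), hazard ratios (1, 5), censoring rate 2.5e-4/day.  Missing values
and zeros can be injected at configurable rates for exercising the filters;
the canonical fixture is clean.  Truth labels are returned separately and
never written into the emitted data files.

What the generator does *not* emulate: count-distributed expression
(negative binomial), beta-valued methylation, batch effects, correlated
feature blocks, or non-proportional hazards.  Passing tests on these
cohorts therefore demonstrate the machinery — preprocessing, losses,
training dynamics, statistics, discovery bookkeeping — not performance on
real cohort noise structure.

## Problem sizes

Tests and the acceptance script run the full pipeline on the 120 × 630
cohort with three seeded training runs per loss and ten runs for the
consensus checks, and validate the Cox machinery on 50 replicates of
n = 500 cohorts plus a 100-column null calibration at n = 300.  These sizes
are the package's chosen desk-scale study conditions; all of them are
configurable upward.

## Known limitations

* The survival branch is linear and unpenalised beyond L1; heavily
  over-parameterised regimes (bottleneck dimension ≈ sample count) can
  still overfit the event ranking with long training.
* Efron ties, multivariate/penalised Cox, time-varying effects and
  competing risks are out of scope.
* The per-epoch silhouette uses the training loop's current assignments;
  re-derived nearest-centroid labels can differ mid-epoch.
* Gene-set enrichment of discovered features requires external annotation
  services and is not part of the package.
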