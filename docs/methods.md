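# Methods

## The quantity being measured

Given a dataset with feature matrix X (N samples × d features) and binary
outcome y, a modeling grid G of (selector, k, classifier-configuration)
cells is evaluated under two training schemes that differ in exactly one
step. Under **Scheme A** the feature selector is scored once on all N
samples — outcome labels included — and the resulting top-k feature set is
reused in every cross-validation fold. Under **Scheme B** the selector is
re-scored inside each fold on the K−1 training folds only. Everything else
(fold split, classifier, hyperparameters, seeds) is held identical, so

    bias = metric(best-by-AUC-ROC model under A) − metric(best under B)

isolates the effect of scoring the selector on data that includes the
validation folds. Metrics are micro-averaged: out-of-fold probability
predictions from all folds are pooled into a single length-N vector before
AUC-ROC, AUC-PR or accuracy is computed, rather than averaging per-fold
metrics. Both schemes share one fold assignment per (dataset, seed); this
pairing removes fold-splitting noise from the A−B difference.

## Cross-validation

Stratified K-fold (default K = 10). Each class is shuffled and dealt
round-robin into folds, with the dealing position carried over between
classes. This guarantees both invariants exactly: total fold sizes differ
by at most one, and per-fold class counts are within one of exact
proportionality. Classes smaller than K are rejected. Classifier seeds are
derived per (experiment seed, fold, configuration) by SHA-256 hashing, so
repeat runs are bitwise stable and no global RNG state is used.

## Preprocessing — deliberately outside the folds

Column-mean imputation followed by z-scoring (population SD, matching
common ML scalers; constant columns map to zeros and are flagged rather
than dropped so feature indices stay aligned across schemes). Both steps
are applied **once to the whole dataset before cross-validation, on
purpose**: neither uses the outcome, and nesting them fold-wise would move
the estimates and occlude the selection-leak signal being measured. The
measured bias is therefore a lower bound — a fully leak-free pipeline would
also nest preprocessing. No outlier removal and no resampling for class
imbalance are performed.

## Feature selectors

All seven are filters producing per-feature relevance scores
(higher = better); selection keeps the top k ∈ {1, 2, 4, 8, 16, 32}
(k capped at d with a warning). Ties break by ascending feature index.
Constant features always receive minimal relevance; infinite univariate
statistics (zero within-class variance, distinct means) are capped just
above the largest finite score.

- **t-score** — |Welch two-sample t|. Welch rather than pooled for
  robustness to unequal class variances.
- **F-score** — one-way ANOVA F; for two groups equal to the squared
  pooled-variance t, so the two rankings can differ (Welch vs pooled).
- **MIM** — plug-in mutual information (nats) between the outcome and the
  feature discretized into 10 equal-frequency bins. Rank-based binning
  makes the score invariant under strictly monotone transforms. The
  plug-in estimator's null bias is ≈ (bins−1)/(2N) nats; it shifts all
  null features equally and does not affect ranking.
- **ReliefF** — all samples as anchors, 10 nearest hits/misses under
  Manhattan distance, differences normalized by feature range. All-anchors
  mode makes the weights invariant to sample order.
- **mRMR** — classic greedy difference criterion: pick argmax of
  (MIM relevance − mean |Pearson correlation| to the already-selected
  set), seeded with the most relevant feature. The ensemble/bootstrap
  variant of mRMR is intentionally not implemented; the greedy form is
  what the scores and tests refer to.
- **LASSO** — L1-logistic path from the analytically computed
  all-zero penalty down by a factor 10³ over 50 geometric steps
  (liblinear); features ranked by first entry into the active set, ties by
  final |coefficient|, never-active features last by final |coefficient|.
- **SVM-RFE** — linear SVC (C = 1) retrained after each elimination round;
  half of the surviving features dropped per round while more than 64
  remain, then one per round. The reversed elimination order is the
  ranking.

## Classifiers

All expose `predict_proba`; probabilities (never margins) are pooled so the
micro-averaged metrics compare like with like. The RBF-SVM obtains
probabilities via Platt calibration. The constant classifier predicts the
training-majority class with probability 1 (ties → class 0); because it
ignores features entirely, its pooled predictions are bitwise identical
under both schemes — a built-in negative control for the whole pipeline.

Default grids are deliberately small (logistic C ∈ {0.01, 0.1, 1, 10};
random forest 100/500 trees × depth {∞, 5}; RBF-SVM C ∈ {0.1, 1, 10} ×
γ ∈ {scale, 0.01}; MLP 16/64 hidden units × L2 {1e-4, 1e-2}; XGBoost depth
{2, 4} × learning rate {0.1, 0.3} × 100 rounds; naive Bayes and constant
have none): the goal is measuring a *difference* between schemes, which a
handful of grid points per classifier already exercises, and grids can be
overridden per experiment. Grid enumeration order is deterministic
(lexicographic) and serves as the tie-break when two models reach the same
metric.

## Statistics

The bootstrap test is paired and two-sided: N sample indices are drawn with
replacement (single-class draws redrawn), the metric recomputed on both
prediction vectors restricted to the draw, and p = 2·min(#{Δ\*≤0},
#{Δ\*≥0})/B, clipped to [2/B, 1], with B = 2000 by default. Identical
prediction vectors give p = 1 exactly. The bias-versus-dimensionality
relationship is summarized by Pearson's R and the OLS slope of bias on N/d,
with the correlation's t-test p-value (n−2 df). p-values are reported raw,
one comparison per dataset; no multiplicity correction is applied.

## Synthetic data generator

Features are drawn from a block-equicorrelated standard normal: each block
of `block_size` consecutive columns shares a latent factor, giving every
within-block pair the requested correlation ρ while keeping unit variances
(x = √ρ·z_block + √(1−ρ)·ε). The outcome has exactly round(N·prevalence)
positives (deterministic class counts simplify stratification edge cases).
The first `n_informative` columns get their mean shifted by `effect_size`
SDs in the positive class; the flag is kept in metadata so recovery tests
can check selectors against ground truth. Missing values are injected
cell-wise at a rate capped at 1%, never blanking an entire column and never
touching the outcome.

The generator emulates the dimensionality (down to ~0.01 samples per
feature), block redundancy, prevalence range (~28–73%) and sparse
missingness of real radiomics tables. It does **not** emulate heavy tails,
feature-scale heterogeneity, nonlinear feature-outcome relations, site or
scanner batch effects, or the empirical correlation structure of real
radiomics features — the block-normal model is an explicit simplification.
Passing tests therefore demonstrate the leakage *mechanism* and the
pipeline's correctness, not the exact magnitude of bias on any real
dataset.

## Problem sizes used in tests and the acceptance script

The null-leakage experiment uses N = 100, d = 1000, prevalence 0.5, t-score
with k = 32, logistic regression, 20 repetitions; the dimensionality sweep
uses d ∈ {20, 200, 2000} at N = 100 with 10 repetitions each (at d = 20 the
k = 32 selector is capped at d, making selection vacuous — the natural
low-dimensional endpoint of the trend); signal recovery uses N = 200,
d = 200, 8 informative features at effect size 1.0, 20 repetitions;
bootstrap calibration uses 200 null trials at N = 200 with 500 resamples.
These sizes give stable means (Monte-Carlo SE of the mean bias ≈ 0.01)
while keeping a full run in the order of a minute.

## Known limitations

- Repeated/leave-one-out/fivefold CV, nested hyperparameter tuning, and
  feature-stability analysis are out of scope.
- The bootstrap is the paired percentile-tail form; DeLong or permutation
  AUC tests are not provided.
- Without an independent validation set the *true* extent of the bias on
  real data cannot be determined; the comparison is between two estimates.
- Accuracy uses a fixed 0.5 probability threshold.
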