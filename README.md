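# cvleak

Measure the optimism bias caused by applying feature selection **before**
cross-validation on high-dimensional tabular data.

## The problem

Radiomics and similar biomarker studies model feature tables with far more
features than samples (often N/d < 0.1). Almost all of them reduce the
feature count with a filter selection method before fitting a classifier,
and almost all of them estimate performance by cross-validation. If the
selector is scored on the *whole* dataset — validation folds and their
labels included — before the folds are split, the validation data has
leaked into training, and the cross-validated performance estimate is
inflated. `cvleak` quantifies exactly how much.

The package runs identical modeling grids under two training schemes:

- **Scheme A (leaky):** the selector is scored once on all N samples; the
  same selected feature set is reused in every fold.
- **Scheme B (correct):** the selector is re-scored inside each fold on the
  K−1 training folds only; no validation sample ever influences which
  features are kept.

Both schemes share one stratified tenfold split, so the difference in
pooled (micro-averaged) metrics isolates the leak. The study-level **bias**
is defined as the best model by AUC-ROC under Scheme A minus the best model
by AUC-ROC under Scheme B:

```
bias = metric( argmax_AUC grid under A ) − metric( argmax_AUC grid under B )
```

reported for AUC-ROC, the area under the precision–recall curve, and
accuracy, with a paired bootstrap test (2000 repeats, two-sided) of the
null hypothesis that the difference is zero, and an OLS regression of bias
on the samples-per-feature ratio N/d.

Seven filter selectors are implemented (t-score, F-score, mutual
information maximization, ReliefF, greedy mRMR, LASSO-path entry order,
SVM-RFE) with k ∈ {1, 2, 4, 8, 16, 32}, and seven classifiers (logistic
regression, random forest, RBF-SVM, neural network, gradient-boosted
trees, Gaussian naive Bayes, and a constant majority-class baseline that
is immune to selection by construction).

A synthetic-data generator produces radiomics-like tables — block-correlated
Gaussian features, configurable prevalence, optional planted signal, sparse
(<1%) missing values — so the whole pipeline is testable without external
downloads. A loader reads real feature tables from CSV (one binary outcome
column, default name `Target`).

## Worked example

`examples/02_leakage_bias_demo.py` builds a pure-noise dataset (100 samples
× 1000 features, no feature associated with the outcome) and runs the same
t-score + logistic-regression model under both schemes:

```
data: 100 samples x 1000 noise features (no true signal)
Scheme A (selection before CV, leaky):   AUC-ROC = 0.915
Scheme B (selection nested in CV, correct): AUC-ROC = 0.501
optimism bias (A - B): +0.414
paired bootstrap p-value (2000 repeats): 0.001
```

On noise, an honest pipeline must score near AUC 0.5 — Scheme B does.
Scheme A reports what looks like a strong biomarker model, produced
entirely by data leakage. The other examples sweep dimensionality
(`03_dimensionality_trend.py`: the bias grows as N/d shrinks, Pearson
R ≈ −0.9 on the sweep) and run a small full grid with best-model
comparison and the per-combination bias matrix (`04_full_grid_experiment.py`).

A thin CLI wraps the same library calls:

```bash
cvleak generate --n-samples 100 --n-features 1000 --seed 7 --out noise.csv
cvleak run noise.csv --selector t_score --k 32 --classifier logistic \
    --classifier constant --out results/
```

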