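"""Micro-averaged metrics, best-model selection and the bias statistics.

All metrics are computed on pooled out-of-fold predictions (one probability
per sample), never averaged across folds.  The bias of the leaky pipeline is
defined at the level a study would report: the best model by AUC-ROC under
Scheme A minus the best model by AUC-ROC under Scheme B, per metric.  A
paired bootstrap over samples attaches a two-sided p-value to each
difference, and an ordinary least-squares regression of bias on the
samples-per-feature ratio quantifies how the bias grows with
dimensionality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy import stats

from .cv import PooledPredictions

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationResult",
    "SchemeComparison",
    "BiasRegressionResult",
    "auc_roc",
    "auc_pr",
    "threshold_metrics",
    "evaluate",
    "select_best",
    "compare_schemes",
    "bootstrap_delta_test",
    "combination_bias",
    "bias_vs_dimensionality",
]

#: metrics reported in scheme comparisons, in reporting order
COMPARED_METRICS = ("auc_roc", "auc_pr", "accuracy")


@dataclass
class EvaluationResult:
    """All metrics of one pooled prediction vector."""

    auc_roc: float
    auc_pr: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    preds: PooledPredictions | None = None

    def metric(self, name: str) -> float:
        return float(getattr(self, name))


@dataclass
class SchemeComparison:
    """Best models of both schemes, their metric differences and p-values."""

    best_a: EvaluationResult
    best_b: EvaluationResult
    delta: dict[str, float]
    p_values: dict[str, float]
    dataset_name: str = "dataset"


@dataclass
class BiasRegressionResult:
    """OLS of bias on samples-per-feature with Pearson correlation."""

    points: list[tuple[float, float]]
    pearson_r: float
    slope: float
    intercept: float
    p_value: float


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present to compute AUC")
    return labels


def _probs_labels(preds) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(preds, PooledPredictions):
        return np.asarray(preds.probs, dtype=float), np.asarray(preds.labels)
    probs, labels = preds
    return np.asarray(probs, dtype=float), np.asarray(labels)


def auc_roc(preds) -> float:
    """Area under the ROC curve with ties counted one half.

    Computed by the Mann-Whitney rank identity: the probability that a
    random positive outscores a random negative, ties contributing 1/2.
    Accepts a PooledPredictions or a (probs, labels) pair.
    """
    probs, labels = _probs_labels(preds)
    labels = _check_labels(labels)
    n_pos = int((labels == 1).sum())
    n_neg = len(labels) - n_pos
    ranks = stats.rankdata(probs)  # average ranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_pr(preds) -> float:
    """Area under the precision-recall curve by the average-precision rule.

    The step-wise rule sums precision at each recall increment over
    descending unique thresholds; it avoids the optimistic linear
    interpolation of the trapezoid rule.
    """
    probs, labels = _probs_labels(preds)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("at least one positive label is required for AUC-PR")
    order = np.argsort(-probs, kind="stable")
    sorted_probs = probs[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(1 - sorted_labels)
    # evaluate only at the last index of each tied threshold block
    last_of_block = np.r_[sorted_probs[1:] != sorted_probs[:-1], True]
    tp_b, fp_b = tp[last_of_block], fp[last_of_block]
    precision = tp_b / (tp_b + fp_b)
    recall = tp_b / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def threshold_metrics(preds, threshold: float = 0.5) -> dict[str, float]:
    """Confusion-matrix metrics at a fixed probability threshold.

    Predicted class is 1 iff prob >= threshold.  Precision of an empty
    positive-prediction set is defined as 0 (and logged).
    """
    probs, labels = _probs_labels(preds)
    labels = np.asarray(labels, dtype=int)
    pred = (probs >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n = len(labels)
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    if tp + fp == 0:
        logger.info("no positive predictions at threshold %g; precision set to 0", threshold)
        prec = 0.0
    else:
        prec = tp / (tp + fp)
    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "recall": sens,
    }


def evaluate(preds: PooledPredictions) -> EvaluationResult:
    """All metrics of one pooled prediction vector."""
    thr = threshold_metrics(preds)
    return EvaluationResult(
        auc_roc=auc_roc(preds),
        auc_pr=auc_pr(preds),
        preds=preds,
        **thr,
    )


def select_best(results: list[EvaluationResult], metric: str = "auc_roc") -> EvaluationResult:
    """The result maximizing ``metric``; ties keep the earliest entry.

    The input order is the stable grid-enumeration order, which makes the
    tie-break deterministic and documented.
    """
    if not results:
        raise ValueError("cannot select the best of an empty result list")
    best = results[0]
    for r in results[1:]:
        if r.metric(metric) > best.metric(metric):
            best = r
    return best


def bootstrap_delta_test(
    preds_a: PooledPredictions,
    preds_b: PooledPredictions,
    metrics: tuple[str, ...] = COMPARED_METRICS,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict[str, float]:
    """Paired bootstrap test of zero metric difference between two models.

    Both prediction vectors must cover the same samples in the same order.
    Each repeat draws N sample indices with replacement, recomputes the
    metric on both vectors restricted to the draw, and records the
    difference; draws with a single outcome class are redrawn.  The
    two-sided p-value is twice the smaller tail fraction of the resampled
    differences around zero, clipped to [2/n_boot, 1].
    """
    if preds_a.probs.shape != preds_b.probs.shape or not np.array_equal(
        preds_a.labels, preds_b.labels
    ):
        raise ValueError("paired bootstrap requires identical samples in both models")
    metric_fns = {"auc_roc": auc_roc, "auc_pr": auc_pr}
    rng = np.random.default_rng(seed)
    n = len(preds_a.labels)
    deltas = {m: np.empty(n_boot) for m in metrics}
    for b in range(n_boot):
        while True:
            idx = rng.integers(n, size=n)
            labels = preds_a.labels[idx]
            if 0 < labels.sum() < n:
                break
        pa, pb = preds_a.probs[idx], preds_b.probs[idx]
        for m in metrics:
            if m in metric_fns:
                va = metric_fns[m]((pa, labels))
                vb = metric_fns[m]((pb, labels))
            else:
                va = threshold_metrics((pa, labels))[m]
                vb = threshold_metrics((pb, labels))[m]
            deltas[m][b] = va - vb
    p_values = {}
    for m in metrics:
        d = deltas[m]
        lo = (d <= 0).sum()
        hi = (d >= 0).sum()
        p = 2.0 * min(lo, hi) / n_boot
        p_values[m] = float(np.clip(p, 2.0 / n_boot, 1.0))
    return p_values


def compare_schemes(
    results_a: list[EvaluationResult],
    results_b: list[EvaluationResult],
    n_boot: int = 2000,
    seed: int = 0,
) -> SchemeComparison:
    """Bias of the leaky scheme: best-A metrics minus best-B metrics.

    Both result lists must come from the same dataset.  The best model of
    each scheme is chosen by AUC-ROC (the primary metric); the per-metric
    differences of those two models are the bias, with paired-bootstrap
    p-values attached.
    """
    if not results_a or not results_b:
        raise ValueError("both schemes need at least one result")
    names = {
        r.preds.dataset_name for r in results_a + results_b if r.preds is not None
    }
    if len(names) > 1:
        raise ValueError(f"results span multiple datasets: {sorted(names)}")
    best_a = select_best(results_a)
    best_b = select_best(results_b)
    delta = {m: best_a.metric(m) - best_b.metric(m) for m in COMPARED_METRICS}
    p_values = bootstrap_delta_test(
        best_a.preds, best_b.preds, n_boot=n_boot, seed=seed
    )
    return SchemeComparison(
        best_a=best_a,
        best_b=best_b,
        delta=delta,
        p_values=p_values,
        dataset_name=names.pop() if names else "dataset",
    )


def combination_bias(
    results: list[EvaluationResult], metric: str = "auc_roc"
):
    """Mean per-(selector, classifier) bias across datasets.

    For each dataset and each selector-method x classifier-name combination,
    the best model by the metric is found within each scheme and the A - B
    difference taken; cells are averaged over datasets, with the min/max
    range retained.  Returns a DataFrame indexed by selector with classifier
    columns; each cell is a dict with mean, range and count.  Combinations
    missing a scheme on every dataset are flagged absent (None).
    """
    import pandas as pd

    by_key: dict[tuple[str, str, str, str], list[EvaluationResult]] = {}
    for r in results:
        if r.preds is None or r.preds.selector is None or r.preds.classifier is None:
            raise ValueError("combination_bias needs provenance on every result")
        key = (
            r.preds.dataset_name,
            r.preds.selector.method,
            r.preds.classifier.name,
            r.preds.scheme,
        )
        by_key.setdefault(key, []).append(r)

    datasets = sorted({k[0] for k in by_key})
    selectors = sorted({k[1] for k in by_key})
    classifiers = sorted({k[2] for k in by_key})
    cells: dict[str, dict[str, Any]] = {}
    for clf in classifiers:
        column: dict[str, Any] = {}
        for sel in selectors:
            diffs = []
            for ds in datasets:
                ra = by_key.get((ds, sel, clf, "A"))
                rb = by_key.get((ds, sel, clf, "B"))
                if ra is None or rb is None:
                    continue
                diffs.append(
                    select_best(ra, metric).metric(metric)
                    - select_best(rb, metric).metric(metric)
                )
            if not diffs:
                column[sel] = None
                continue
            column[sel] = {
                "mean": float(np.mean(diffs)),
                "range": (float(min(diffs)), float(max(diffs))),
                "n_datasets": len(diffs),
            }
        cells[clf] = column
    return pd.DataFrame(cells).reindex(index=selectors, columns=classifiers)


def bias_vs_dimensionality(points: list[tuple[float, float]]) -> BiasRegressionResult:
    """Regress observed bias on the samples-per-feature ratio.

    Returns the Pearson correlation, OLS slope and intercept, and the
    two-sided p-value of the correlation (t-distributed with n - 2 degrees
    of freedom).  A negative correlation means datasets with fewer samples
    per feature show larger leakage bias.
    """
    if len(points) < 3:
        raise ValueError("at least 3 (samples-per-feature, bias) points are required")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.all(x == x[0]):
        raise ValueError("samples-per-feature values are constant; regression undefined")
    fit = stats.linregress(x, y)
    return BiasRegressionResult(
        points=[(float(a), float(b)) for a, b in points],
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
    )
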