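"""Stratified k-fold splitting and the two training schemes.

The leakage experiment compares two pipelines that differ in exactly one
place.  Under Scheme A (leaky) the feature selector is scored once on the
*whole* dataset — outcome labels of every sample included — and the same
selected feature set is reused in every fold.  Under Scheme B (correct) the
selector is re-scored inside each fold on the training portion only, so no
validation sample ever influences which features are kept.  Both schemes
share one fold assignment, so the difference between their pooled metrics
isolates the selection leak rather than fold-splitting noise.

Out-of-fold probability predictions are pooled into a single vector per run
(micro-averaging); metrics are computed on that vector downstream.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import feature_selection as fs
from . import models
from .datasets import RadiomicsDataset
from .feature_selection import SelectorConfig
from .models import ClassifierConfig

__all__ = [
    "FoldAssignment",
    "PooledPredictions",
    "stratified_kfold",
    "run_scheme_a",
    "run_scheme_b",
    "run_scheme",
]


@dataclass
class FoldAssignment:
    """Assignment of each sample to one of K folds."""

    fold_of: np.ndarray
    K: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


@dataclass
class PooledPredictions:
    """One out-of-fold probability per sample, with labels and provenance."""

    probs: np.ndarray
    labels: np.ndarray
    fold_of: np.ndarray
    scheme: str
    dataset_name: str = "dataset"
    selector: SelectorConfig | None = None
    classifier: ClassifierConfig | None = None
    selected_features: dict[int, np.ndarray] = field(default_factory=dict)


def stratified_kfold(y: np.ndarray, K: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified fold assignment by within-class shuffled round-robin.

    Each class is shuffled and dealt round-robin; the dealing position
    carries over between classes so overall fold sizes also differ by at
    most one.  Per-fold class counts are within one of exact
    proportionality by construction.
    """
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(y), dtype=int)
    offset = 0
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < K:
            raise ValueError(
                f"class {cls} has only {len(idx)} members; need at least K={K}"
            )
        rng.shuffle(idx)
        fold_of[idx] = (offset + np.arange(len(idx))) % K
        offset = (offset + len(idx)) % K
    return FoldAssignment(fold_of=fold_of, K=K, seed=seed)


def derive_seed(*parts: Any) -> int:
    """Stable sub-seed from arbitrary labeled parts (no global RNG state)."""
    text = "|".join(str(p) for p in parts)
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _fit_predict_fold(
    dataset: RadiomicsDataset,
    clf: ClassifierConfig,
    folds: FoldAssignment,
    fold: int,
    columns: np.ndarray,
    experiment_seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    train_idx = folds.train_indices(fold)
    test_idx = folds.test_indices(fold)
    fold_seed = derive_seed(experiment_seed, fold, clf.label())
    model = models.fit(
        clf.with_seed(fold_seed),
        dataset.features[np.ix_(train_idx, columns)],
        dataset.outcome[train_idx],
    )
    probs = model.predict_proba(dataset.features[np.ix_(test_idx, columns)])
    return test_idx, probs


def run_scheme_a(
    dataset: RadiomicsDataset,
    selector: SelectorConfig,
    clf: ClassifierConfig,
    folds: FoldAssignment,
    seed: int = 0,
) -> PooledPredictions:
    """Leaky pipeline: features selected once on all samples, labels included.

    The selector sees every outcome label before any fold is held out — the
    deliberate leak being measured.  The classifier itself is still trained
    fold-wise on training data only.
    """
    score = fs.score_features(
        dataset.features, dataset.outcome, selector, seed=derive_seed(seed, "select")
    )
    columns = fs.select_top_k(score, selector.k)
    probs = np.empty(dataset.n_samples)
    selected: dict[int, np.ndarray] = {}
    for fold in range(folds.K):
        test_idx, p = _fit_predict_fold(dataset, clf, folds, fold, columns, seed)
        probs[test_idx] = p
        selected[fold] = columns
    return PooledPredictions(
        probs=probs,
        labels=dataset.outcome.copy(),
        fold_of=folds.fold_of.copy(),
        scheme="A",
        dataset_name=dataset.name,
        selector=selector,
        classifier=clf,
        selected_features=selected,
    )


def run_scheme_b(
    dataset: RadiomicsDataset,
    selector: SelectorConfig,
    clf: ClassifierConfig,
    folds: FoldAssignment,
    seed: int = 0,
) -> PooledPredictions:
    """Correct pipeline: features re-selected inside each fold.

    The selector is scored K times, each time on the K-1 training folds
    only; the held-out fold is predicted with that fold's own feature set.
    No validation sample contributes to feature selection.
    """
    probs = np.empty(dataset.n_samples)
    selected: dict[int, np.ndarray] = {}
    for fold in range(folds.K):
        train_idx = folds.train_indices(fold)
        score = fs.score_features(
            dataset.features[train_idx],
            dataset.outcome[train_idx],
            selector,
            seed=derive_seed(seed, "select", fold),
        )
        columns = fs.select_top_k(score, selector.k)
        test_idx, p = _fit_predict_fold(dataset, clf, folds, fold, columns, seed)
        probs[test_idx] = p
        selected[fold] = columns
    return PooledPredictions(
        probs=probs,
        labels=dataset.outcome.copy(),
        fold_of=folds.fold_of.copy(),
        scheme="B",
        dataset_name=dataset.name,
        selector=selector,
        classifier=clf,
        selected_features=selected,
    )


def run_scheme(scheme: str, *args, **kwargs) -> PooledPredictions:
    if scheme.upper() == "A":
        return run_scheme_a(*args, **kwargs)
    if scheme.upper() == "B":
        return run_scheme_b(*args, **kwargs)
    raise ValueError(f"scheme must be 'A' or 'B', got {scheme!r}")
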