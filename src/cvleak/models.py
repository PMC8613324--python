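"""Classifiers behind a single fit / predict-probability contract.

Seven classifiers: logistic regression, random forest, RBF-kernel SVM, a
one-hidden-layer neural network, gradient-boosted trees, Gaussian naive
Bayes, and a constant majority-class baseline.  Every model emits a
probability of the positive class so pooled cross-validation metrics
compare like with like (the SVM uses its internal probability calibration;
raw margins are never pooled).  The constant baseline ignores the features
entirely, so it cannot be affected by feature selection — it anchors the
leakage comparison at exactly zero bias.

Hyperparameter grids are small by design: tuning a handful of values per
classifier keeps the full selector x k x classifier grid tractable while
still exercising model selection.  Grids can be overridden per classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "CLASSIFIER_NAMES",
    "DEFAULT_GRIDS",
    "ClassifierConfig",
    "FittedModel",
    "enumerate_grid",
    "fit",
]

CLASSIFIER_NAMES = (
    "constant",
    "logistic",
    "naive_bayes",
    "neural_net",
    "random_forest",
    "rbf_svm",
    "xgb_tree",
)

DEFAULT_GRIDS: dict[str, dict[str, list[Any]]] = {
    "logistic": {"C": [0.01, 0.1, 1.0, 10.0]},
    "random_forest": {"n_estimators": [100, 500], "max_depth": [None, 5]},
    "rbf_svm": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01]},
    "neural_net": {"hidden_units": [16, 64], "alpha": [1e-4, 1e-2]},
    "xgb_tree": {"max_depth": [2, 4], "n_estimators": [100], "learning_rate": [0.1, 0.3]},
    "naive_bayes": {},
    "constant": {},
}


@dataclass(frozen=True)
class ClassifierConfig:
    name: str
    hyperparameters: tuple[tuple[str, Any], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.name!r}; choose from {CLASSIFIER_NAMES}"
            )

    @property
    def params(self) -> dict[str, Any]:
        return dict(self.hyperparameters)

    def with_seed(self, seed: int) -> "ClassifierConfig":
        return ClassifierConfig(self.name, self.hyperparameters, seed)

    def label(self) -> str:
        """Stable human-readable identifier used in results tables."""
        if not self.hyperparameters:
            return self.name
        inner = ",".join(f"{k}={v}" for k, v in self.hyperparameters)
        return f"{self.name}({inner})"


def enumerate_grid(
    names: list[str] | tuple[str, ...],
    grid_overrides: dict[str, dict[str, list[Any]]] | None = None,
    seed: int = 0,
) -> list[ClassifierConfig]:
    """All hyperparameter configurations for the requested classifiers.

    The ordering is deterministic — classifiers sorted by name, parameters
    by key, values in grid order — and serves as the tie-break when two
    models reach the same metric downstream.
    """
    overrides = grid_overrides or {}
    configs: list[ClassifierConfig] = []
    for name in sorted(names):
        if name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}"
            )
        grid = overrides.get(name, DEFAULT_GRIDS[name])
        keys = sorted(grid)
        if not keys:
            configs.append(ClassifierConfig(name=name, seed=seed))
            continue
        for values in product(*(grid[k] for k in keys)):
            configs.append(
                ClassifierConfig(
                    name=name,
                    hyperparameters=tuple(zip(keys, values)),
                    seed=seed,
                )
            )
    return configs


class _ConstantMajority:
    """Predicts the training-majority class with probability 1; ties -> 0."""

    def fit(self, X, y):
        y = np.asarray(y)
        n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
        self.majority_ = 1 if n_pos > n_neg else 0
        return self

    def predict_proba(self, X):
        p = np.zeros((np.asarray(X).shape[0], 2))
        p[:, self.majority_] = 1.0
        return p


@dataclass
class FittedModel:
    """A trained classifier honoring the probability contract."""

    config: ClassifierConfig
    estimator: Any

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class for each row of X."""
        X = np.asarray(X, dtype=float)
        proba = self.estimator.predict_proba(X)
        classes = getattr(self.estimator, "classes_", np.array([0, 1]))
        col = int(np.flatnonzero(classes == 1)[0]) if 1 in classes else None
        if col is None:
            # positive class absent from training (constant classifier only)
            out = np.zeros(X.shape[0])
        else:
            out = proba[:, col]
        return np.clip(out, 0.0, 1.0)


def _build_estimator(config: ClassifierConfig):
    p = config.params
    seed = config.seed
    name = config.name
    if name == "constant":
        return _ConstantMajority()
    if name == "logistic":
        return LogisticRegression(C=p.get("C", 1.0), max_iter=1000, random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 100),
            max_depth=p.get("max_depth"),
            random_state=seed,
        )
    if name == "rbf_svm":
        # probabilities via internal Platt calibration; raw margins are never pooled
        from sklearn.calibration import CalibratedClassifierCV

        svc = SVC(kernel="rbf", C=p.get("C", 1.0), gamma=p.get("gamma", "scale"))
        return CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)
    if name == "neural_net":
        return MLPClassifier(
            hidden_layer_sizes=(p.get("hidden_units", 16),),
            alpha=p.get("alpha", 1e-4),
            max_iter=500,
            random_state=seed,
        )
    if name == "xgb_tree":
        return XGBClassifier(
            max_depth=p.get("max_depth", 2),
            n_estimators=p.get("n_estimators", 100),
            learning_rate=p.get("learning_rate", 0.1),
            random_state=seed,
            eval_metric="logloss",
            verbosity=0,
        )
    raise ValueError(f"unknown classifier {name!r}")


def fit(config: ClassifierConfig, X_train: np.ndarray, y_train: np.ndarray) -> FittedModel:
    """Train ``config`` on the given data.

    Non-constant classifiers require both classes in ``y_train``; the
    constant baseline only needs one sample.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if y_train.size == 0:
        raise ValueError("empty training set")
    if config.name != "constant" and len(np.unique(y_train)) < 2:
        raise ValueError(
            f"classifier {config.name!r} needs both classes in the training data"
        )
    estimator = _build_estimator(config)
    estimator.fit(X_train, y_train)
    return FittedModel(config=config, estimator=estimator)
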