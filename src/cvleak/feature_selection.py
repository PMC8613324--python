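"""Filter feature-selection methods and top-k selection.

Seven scorers are provided: univariate t-score and F-score, mutual
information maximization (MIM), ReliefF, greedy minimum-redundancy
maximum-relevance (mRMR), LASSO-path entry order, and SVM-RFE.  All are
filters: each yields a per-feature relevance score (higher = better) from
which the best k features are taken, independently of the downstream
classifier.  Methods whose natural output is an ordering rather than a
score (mRMR, LASSO, SVM-RFE) additionally carry an explicit
``selected_order`` which top-k selection uses directly.

Degenerate cases follow one rule everywhere: constant (zero-variance)
features receive the minimal relevance, and infinite univariate statistics
(zero within-class variance with distinct class means) are capped just
above the largest finite score, deterministically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "SELECTOR_METHODS",
    "K_GRID",
    "SelectorConfig",
    "FeatureScore",
    "score_t",
    "score_f",
    "score_mim",
    "score_relieff",
    "score_mrmr",
    "score_lasso",
    "score_svm_rfe",
    "score_features",
    "select_top_k",
]

SELECTOR_METHODS = ("lasso", "t_score", "f_score", "mrmr", "relieff", "mim", "svm_rfe")
#: feature counts searched over in the modeling grid
K_GRID = (1, 2, 4, 8, 16, 32)


@dataclass(frozen=True)
class SelectorConfig:
    """A named scoring method plus the number of features to keep."""

    method: str
    k: int

    def __post_init__(self) -> None:
        if self.method not in SELECTOR_METHODS:
            raise ValueError(
                f"unknown selector {self.method!r}; choose from {SELECTOR_METHODS}"
            )
        if self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")


@dataclass
class FeatureScore:
    """Per-feature relevance scores, higher = more relevant.

    ``selected_order`` is set by methods that produce an explicit ranking
    (mrmr, lasso, svm_rfe); when present, top-k selection takes its prefix.
    """

    scores: np.ndarray
    method: str
    selected_order: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("feature scores must all be finite")


def _check_classes(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    pos, neg = y == 1, y == 0
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("both outcome classes must be present for scoring")
    return pos, neg


def _cap_infinite(scores: np.ndarray) -> np.ndarray:
    """Replace +inf by (largest finite score + 1), NaN by 0."""
    scores = np.where(np.isnan(scores), 0.0, scores)
    inf = np.isinf(scores)
    if inf.any():
        finite = scores[~inf]
        cap = (finite.max() if finite.size else 0.0) + 1.0
        scores = np.where(inf, cap, scores)
    return scores


def score_t(X: np.ndarray, y: np.ndarray) -> FeatureScore:
    """Absolute Welch two-sample t statistic per feature.

    Welch's form (unequal variances) is used for robustness; the absolute
    value makes the score symmetric under label swap.  Features with zero
    variance in both classes score 0; an infinite statistic (perfect
    within-class constancy with distinct means) is capped deterministically.
    """
    X = np.asarray(X, dtype=float)
    pos, neg = _check_classes(y)
    n1, n0 = pos.sum(), neg.sum()
    m1, m0 = X[pos].mean(axis=0), X[neg].mean(axis=0)
    v1 = X[pos].var(axis=0, ddof=1) if n1 > 1 else np.zeros(X.shape[1])
    v0 = X[neg].var(axis=0, ddof=1) if n0 > 1 else np.zeros(X.shape[1])
    se = np.sqrt(v1 / n1 + v0 / n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m1 - m0) / se
    t[(se == 0.0) & (m1 == m0)] = 0.0
    return FeatureScore(scores=_cap_infinite(t), method="t_score")


def score_f(X: np.ndarray, y: np.ndarray) -> FeatureScore:
    """One-way ANOVA F statistic per feature.

    For a binary outcome F equals the square of the pooled-variance t
    statistic, so its ranking agrees with a pooled t-test.
    """
    X = np.asarray(X, dtype=float)
    pos, neg = _check_classes(y)
    n = X.shape[0]
    n1, n0 = pos.sum(), neg.sum()
    m, m1, m0 = X.mean(axis=0), X[pos].mean(axis=0), X[neg].mean(axis=0)
    ss_between = n1 * (m1 - m) ** 2 + n0 * (m0 - m) ** 2
    ss_within = ((X[pos] - m1) ** 2).sum(axis=0) + ((X[neg] - m0) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_between / (ss_within / (n - 2))
    f[ss_between == 0.0] = 0.0
    return FeatureScore(scores=_cap_infinite(f), method="f_score")


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize by rank into at most n_bins (nearly) equal-count bins."""
    order = np.argsort(x, kind="stable")
    bins = np.empty(len(x), dtype=int)
    bins[order] = np.arange(len(x)) * n_bins // len(x)
    # merge bins split across tied values: give ties the bin of their first
    sorted_x = x[order]
    sorted_bins = bins[order]
    for i in range(1, len(x)):
        if sorted_x[i] == sorted_x[i - 1]:
            sorted_bins[i] = sorted_bins[i - 1]
    bins[order] = sorted_bins
    return bins


def score_mim(X: np.ndarray, y: np.ndarray, n_bins: int = 10) -> FeatureScore:
    """Empirical mutual information (nats) of each feature with the outcome.

    Features are discretized into ``n_bins`` equal-frequency bins (ties share
    a bin, making the score invariant under strictly monotone transforms);
    MI is the plug-in estimate on the resulting contingency table with the
    outcome.  The plug-in estimator has a positive bias of roughly
    (bins - 1) / (2N) nats on independent data.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    X = np.asarray(X, dtype=float)
    _check_classes(y)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    p_y = np.bincount(y, minlength=2) / n
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        b = _equal_frequency_bins(X[:, j], n_bins)
        # contingency over (bin, outcome)
        joint = np.zeros((b.max() + 1, 2))
        np.add.at(joint, (b, y), 1.0)
        joint /= n
        p_b = joint.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = joint / (p_b[:, None] * p_y[None, :])
            terms = np.where(joint > 0, joint * np.log(ratio), 0.0)
        scores[j] = max(terms.sum(), 0.0)
    return FeatureScore(scores=scores, method="mim")


def score_relieff(
    X: np.ndarray,
    y: np.ndarray,
    n_neighbors: int = 10,
    n_anchors: int | None = None,
    seed: int = 0,
) -> FeatureScore:
    """ReliefF feature weights under Manhattan distance.

    For each anchor sample the ``n_neighbors`` nearest same-class (hits) and
    other-class (misses) neighbors are found; each feature's weight
    accumulates the range-normalized miss-difference minus hit-difference,
    averaged over anchors and neighbors.  By default every sample is an
    anchor, which makes the weights independent of sample order; a random
    subset of ``n_anchors`` anchors can be drawn for speed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_classes(y)
    n, d = X.shape
    for cls in (0, 1):
        if (y == cls).sum() <= n_neighbors:
            raise ValueError(
                f"class {cls} has {(y == cls).sum()} members; "
                f"need more than n_neighbors={n_neighbors}"
            )
    rng = np.random.default_rng(seed)
    if n_anchors is None or n_anchors >= n:
        anchors = np.arange(n)
    else:
        anchors = rng.choice(n, size=n_anchors, replace=False)

    span = X.max(axis=0) - X.min(axis=0)
    safe_span = np.where(span > 0, span, 1.0)  # constant features contribute 0
    weights = np.zeros(d)
    for i in anchors:
        diffs = np.abs(X - X[i])  # n x d
        dist = diffs.sum(axis=1)
        dist[i] = np.inf  # exclude self
        same = y == y[i]
        hit_idx = np.flatnonzero(same)
        miss_idx = np.flatnonzero(~same)
        hits = hit_idx[np.argsort(dist[hit_idx], kind="stable")[:n_neighbors]]
        misses = miss_idx[np.argsort(dist[miss_idx], kind="stable")[:n_neighbors]]
        weights += (diffs[misses] / safe_span).sum(axis=0)
        weights -= (diffs[hits] / safe_span).sum(axis=0)
    weights /= len(anchors) * n_neighbors
    return FeatureScore(scores=weights, method="relieff")


def score_mrmr(X: np.ndarray, y: np.ndarray, k: int, n_bins: int = 10) -> FeatureScore:
    """Greedy minimum-redundancy maximum-relevance selection.

    Relevance of a feature is its MIM mutual information with the outcome;
    redundancy against the already-selected set is the mean absolute Pearson
    correlation.  The greedy criterion (difference form) picks, at each step,
    the unselected feature maximizing relevance minus redundancy, starting
    from the single most relevant feature.  Scores encode pick rank; ties
    break by ascending feature index.
    """
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    if k > d:
        raise ValueError(f"k={k} exceeds the number of features d={d}")
    relevance = score_mim(X, y, n_bins=n_bins).scores
    with np.errstate(invalid="ignore"):
        sd = X.std(axis=0)
    selected: list[int] = [int(np.argmax(relevance))]
    candidates = np.ones(d, dtype=bool)
    candidates[selected[0]] = False
    abs_corr_sum = np.zeros(d)
    for _ in range(1, k):
        last = selected[-1]
        # incremental |corr| of every feature with the latest pick
        xc = X - X.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = (xc * xc[:, [last]]).mean(axis=0) / (sd * sd[last])
        corr = np.where(np.isfinite(corr), np.abs(corr), 1.0)  # constant: fully redundant
        abs_corr_sum += corr
        criterion = relevance - abs_corr_sum / len(selected)
        criterion[~candidates] = -np.inf
        pick = int(np.argmax(criterion))  # argmax is first-index on ties
        selected.append(pick)
        candidates[pick] = False
    order = np.asarray(selected, dtype=int)
    scores = _scores_from_order(order, d, tail_key=relevance)
    return FeatureScore(scores=scores, method="mrmr", selected_order=order)


def _scores_from_order(
    order: np.ndarray, d: int, tail_key: np.ndarray | None = None
) -> np.ndarray:
    """Encode an explicit (possibly partial) ranking as descending scores.

    Ranked features get scores d, d-1, ...; unranked features fill the tail,
    ordered by ``tail_key`` (descending) when given, else by index.
    """
    scores = np.zeros(d)
    scores[order] = d - np.arange(len(order), dtype=float)
    rest = np.setdiff1d(np.arange(d), order)
    if rest.size:
        if tail_key is not None:
            rest = rest[np.argsort(-tail_key[rest], kind="stable")]
        scores[rest] = d - len(order) - np.arange(rest.size, dtype=float)
    return scores


def score_lasso(
    X: np.ndarray, y: np.ndarray, n_steps: int = 50, path_span: float = 1e3
) -> FeatureScore:
    """Rank features by their entry order on the L1-logistic penalty path.

    The path starts at the smallest penalty strength that keeps every
    coefficient at zero (computed from the gradient of the null model) and
    relaxes geometrically by a factor ``path_span`` over ``n_steps`` steps.
    Features are ranked by the step at which they first enter the active
    set; ties break by larger absolute coefficient at the weakest penalty,
    and features that never activate rank last, ordered by their final
    absolute coefficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_classes(y)
    n, d = X.shape
    # gradient of the log-likelihood at zero coefficients (intercept-only fit)
    grad0 = np.abs(X.T @ (y - y.mean()))
    gmax = grad0.max()
    if gmax == 0.0:
        return FeatureScore(
            scores=np.zeros(d), method="lasso", selected_order=np.arange(d)
        )
    # sklearn's objective is ||w||_1 + C * loss: all-zero solution for C <= 1/gmax
    c_min = 1.0 / gmax
    cs = c_min * np.logspace(0, np.log10(path_span), n_steps)
    entry_step = np.full(d, np.inf)
    coef = np.zeros(d)
    for step, c in enumerate(cs):
        model = LogisticRegression(
            l1_ratio=1.0, C=c, solver="liblinear", max_iter=1000, tol=1e-6
        )
        try:
            model.fit(X, y)
        except Exception as exc:  # pragma: no cover - solver failure is exotic
            raise RuntimeError(
                f"L1 path optimization failed at penalty step {step} (C={c:.4g})"
            ) from exc
        coef = model.coef_.ravel()
        newly = (np.abs(coef) > 1e-10) & ~np.isfinite(entry_step)
        entry_step[newly] = step
    # order: earlier entry first; ties by |final coef| desc; never-active last
    final_abs = np.abs(coef)
    order = np.lexsort((np.arange(d), -final_abs, entry_step))
    scores = _scores_from_order(np.asarray(order), d)
    return FeatureScore(scores=scores, method="lasso", selected_order=np.asarray(order))


def score_svm_rfe(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> FeatureScore:
    """SVM recursive feature elimination ranking.

    A linear soft-margin SVM is trained repeatedly; features are ranked by
    squared weight and the weakest are dropped — half at a time while more
    than 64 features remain, then one per iteration.  The reverse of the
    elimination order is the ranking (last survivor = most relevant).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_classes(y)
    d = X.shape[1]
    remaining = list(range(d))
    eliminated: list[int] = []
    while len(remaining) > 1:
        svm = SVC(kernel="linear", C=C)
        svm.fit(X[:, remaining], y)
        w2 = np.ravel(svm.coef_) ** 2
        # drop weakest; ties resolved toward the lower feature index
        order = np.lexsort((remaining, w2))
        n_drop = len(remaining) // 2 if len(remaining) > 64 else 1
        for pos in order[:n_drop]:
            eliminated.append(remaining[pos])
        remaining = [f for f in remaining if f not in set(eliminated)]
    eliminated.extend(remaining)
    ranking = np.asarray(eliminated[::-1], dtype=int)
    scores = _scores_from_order(ranking, d)
    return FeatureScore(scores=scores, method="svm_rfe", selected_order=ranking)


def score_features(
    X: np.ndarray, y: np.ndarray, config: SelectorConfig, seed: int = 0
) -> FeatureScore:
    """Dispatch to the scorer named in ``config``."""
    method = config.method
    if method == "t_score":
        return score_t(X, y)
    if method == "f_score":
        return score_f(X, y)
    if method == "mim":
        return score_mim(X, y)
    if method == "relieff":
        n_nb = min(10, (np.asarray(y) == 0).sum() - 1, (np.asarray(y) == 1).sum() - 1)
        return score_relieff(X, y, n_neighbors=max(1, n_nb), seed=seed)
    if method == "mrmr":
        return score_mrmr(X, y, k=min(config.k, X.shape[1]))
    if method == "lasso":
        return score_lasso(X, y)
    if method == "svm_rfe":
        return score_svm_rfe(X, y)
    raise ValueError(f"unknown selector method {method!r}")


def select_top_k(score: FeatureScore, k: int) -> np.ndarray:
    """Indices of the k highest-scoring features, ascending-index tie-break.

    Methods with an explicit ranking contribute its first k entries.  k is
    capped at the number of features with a warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    d = len(score.scores)
    if k > d:
        warnings.warn(f"k={k} capped at the number of features d={d}", stacklevel=2)
        logger.warning("k=%d capped at d=%d", k, d)
        k = d
    if score.selected_order is not None and len(score.selected_order) >= k:
        return np.sort(np.asarray(score.selected_order[:k], dtype=int))
    order = np.lexsort((np.arange(d), -score.scores))
    return np.sort(order[:k])
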