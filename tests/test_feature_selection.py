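import numpy as np
import pytest
from sklearn.feature_selection import f_classif

from cvleak import DatasetSpec, SelectorConfig, generate_dataset, preprocess
from cvleak.feature_selection import (
    score_f,
    score_features,
    score_lasso,
    score_mim,
    score_mrmr,
    score_relieff,
    score_svm_rfe,
    score_t,
    select_top_k,
)

ALL_SCORERS = {
    "t_score": lambda X, y: score_t(X, y),
    "f_score": lambda X, y: score_f(X, y),
    "mim": lambda X, y: score_mim(X, y),
    "relieff": lambda X, y: score_relieff(X, y, n_neighbors=5, seed=0),
    "mrmr": lambda X, y: score_mrmr(X, y, k=X.shape[1]),
    "lasso": lambda X, y: score_lasso(X, y),
    "svm_rfe": lambda X, y: score_svm_rfe(X, y),
}


class TestTScore:
    def test_welch_statistic_by_hand(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0, 0, 1, 1])
        score = score_t(X, y)
        # means 1.5 vs 3.5, sample variances 0.5 each -> |t| = 2/sqrt(0.5)
        np.testing.assert_allclose(score.scores[0], 2 / np.sqrt(0.5))

    def test_constant_feature_scores_zero(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = np.array([0] * 5 + [1] * 5)
        assert score_t(X, y).scores[0] == 0.0

    def test_label_swap_symmetry(self, rng):
        X = rng.normal(size=(30, 8))
        y = np.array([0] * 15 + [1] * 15)
        np.testing.assert_allclose(
            score_t(X, y).scores, score_t(X, 1 - y).scores
        )

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="class"):
            score_t(rng.normal(size=(10, 3)), np.zeros(10, dtype=int))


class TestFScore:
    def test_rank_order_matches_pooled_t_squared(self, rng):
        # for two groups, F equals the square of the pooled-variance t
        for _ in range(50):
            n = int(rng.integers(20, 60))
            X = rng.normal(size=(n, 12))
            y = (rng.random(n) < 0.5).astype(int)
            if y.sum() in (0, n):
                continue
            f = score_f(X, y).scores
            sk_f = f_classif(X, y)[0]
            assert np.array_equal(np.argsort(f), np.argsort(sk_f))
            np.testing.assert_allclose(f, sk_f, rtol=1e-8)

    def test_perfectly_separated_feature_capped_finite(self):
        X = np.column_stack([
            np.array([0.0] * 5 + [1.0] * 5),  # no within-class variance
            np.random.default_rng(0).normal(size=10),
        ])
        y = np.array([0] * 5 + [1] * 5)
        scores = score_f(X, y).scores
        assert np.isfinite(scores).all()
        assert scores[0] > scores[1]


class TestMim:
    def test_perfect_association_gives_ln2(self):
        y = np.array([0, 1] * 10)
        X = y.reshape(-1, 1).astype(float)
        score = score_mim(X, y, n_bins=2)
        np.testing.assert_allclose(score.scores[0], np.log(2), atol=1e-12)

    def test_independent_feature_has_small_positive_bias(self, rng):
        # plug-in MI bias on null data is about (bins - 1) / (2N) nats
        n, bins = 200, 10
        X = rng.normal(size=(n, 50))
        y = np.array([0, 1] * (n // 2))
        mean_mi = score_mim(X, y, n_bins=bins).scores.mean()
        assert mean_mi < 3 * (bins - 1) / (2 * n)

    def test_monotone_transform_invariance(self, rng):
        X = rng.normal(size=(60, 5))
        y = (rng.random(60) < 0.5).astype(int)
        y[:2] = [0, 1]
        base = score_mim(X, y).scores
        transformed = score_mim(np.exp(X), y).scores
        np.testing.assert_allclose(base, transformed, atol=1e-12)


class TestReliefF:
    def test_separating_feature_beats_noise(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = np.array([0] * 20 + [1] * 20)
            X = np.column_stack([y.astype(float), rng.normal(size=40)])
            w = score_relieff(X, y, n_neighbors=5, seed=seed).scores
            assert w[0] > w[1]

    def test_constant_feature_has_zero_weight(self, rng):
        y = np.array([0] * 15 + [1] * 15)
        X = np.column_stack([np.full(30, 3.0), rng.normal(size=30)])
        assert score_relieff(X, y, n_neighbors=5).scores[0] == 0.0

    def test_sample_permutation_invariance_with_all_anchors(self, rng):
        y = np.array([0] * 15 + [1] * 15)
        X = rng.normal(size=(30, 6))
        perm = rng.permutation(30)
        w1 = score_relieff(X, y, n_neighbors=5).scores
        w2 = score_relieff(X[perm], y[perm], n_neighbors=5).scores
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_small_class_rejected(self, rng):
        y = np.array([0] * 3 + [1] * 20)
        with pytest.raises(ValueError, match="class 0"):
            score_relieff(rng.normal(size=(23, 4)), y, n_neighbors=5)


class TestMrmr:
    def test_first_pick_is_max_relevance(self, rng):
        X = rng.normal(size=(80, 10))
        y = (rng.random(80) < 0.5).astype(int)
        y[:2] = [0, 1]
        order = score_mrmr(X, y, k=5).selected_order
        relevance = score_mim(X, y).scores
        assert order[0] == np.argmax(relevance)

    def test_exact_duplicate_is_skipped_for_weaker_independent_signal(self, rng):
        n = 100
        y = np.array([0, 1] * (n // 2))
        a = y + rng.normal(scale=0.3, size=n)      # strong signal
        b = y + rng.normal(scale=1.2, size=n)      # weaker independent signal
        X = np.column_stack([a, a.copy(), b])      # feature 1 duplicates feature 0
        order = list(score_mrmr(X, y, k=2).selected_order)
        assert order[0] in (0, 1)
        assert order[1] == 2  # redundancy 1 with the duplicate dominates

    def test_k_equals_d_yields_full_permutation(self, rng):
        X = rng.normal(size=(40, 7))
        y = np.array([0, 1] * 20)
        order = score_mrmr(X, y, k=7).selected_order
        assert sorted(order) == list(range(7))


class TestLasso:
    def test_informative_feature_enters_path_first(self):
        wins = 0
        for seed in range(20):
            ds = generate_dataset(
                DatasetSpec(n_samples=200, n_features=21, prevalence=0.5,
                            n_informative=1, effect_size=2.0, seed=seed)
            )
            pp, _ = preprocess(ds)
            order = score_lasso(pp.features, pp.outcome).selected_order
            wins += order[0] == 0
        assert wins >= 19  # informative first in at least 95% of seeds

    def test_duplicated_informative_feature_both_rank_above_noise(self, rng):
        n = 200
        y = np.array([0, 1] * (n // 2))
        signal = y + rng.normal(scale=0.5, size=n)
        X = np.column_stack([signal, signal, rng.normal(size=(n, 10))])
        X = (X - X.mean(0)) / X.std(0)
        score = score_lasso(X, y)
        ranks = np.empty(12, dtype=int)
        ranks[score.selected_order] = np.arange(12)
        assert ranks[0] == 0 or ranks[1] == 0  # one duplicate enters first
        assert max(ranks[0], ranks[1]) < 12  # both are ranked

    def test_all_noise_falls_back_to_final_coefficients(self, rng):
        X = rng.normal(size=(50, 8))
        X = (X - X.mean(0)) / X.std(0)
        y = np.array([0, 1] * 25)
        score = score_lasso(X, y)
        assert len(score.selected_order) == 8
        assert sorted(score.selected_order) == list(range(8))


class TestSvmRfe:
    def test_separating_feature_survives_to_the_end(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = np.array([0] * 20 + [1] * 20)
            X = np.column_stack([2.0 * y - 1.0, rng.normal(size=40)])
            order = score_svm_rfe(X, y).selected_order
            assert order[0] == 0

    def test_single_feature_degenerate(self):
        y = np.array([0] * 5 + [1] * 5)
        X = np.arange(10.0).reshape(-1, 1)
        score = score_svm_rfe(X, y)
        assert list(score.selected_order) == [0]

    def test_elimination_order_is_a_permutation(self, rng):
        X = rng.normal(size=(40, 100))
        y = np.array([0, 1] * 20)
        order = score_svm_rfe(X, y).selected_order
        assert sorted(order) == list(range(100))


class TestSelectTopK:
    def test_highest_scores_selected(self):
        from cvleak.feature_selection import FeatureScore
        score = FeatureScore(scores=np.array([0.9, 0.1, 0.5]), method="t_score")
        assert set(select_top_k(score, 2)) == {0, 2}

    def test_ties_break_by_ascending_index(self):
        from cvleak.feature_selection import FeatureScore
        score = FeatureScore(scores=np.array([1.0, 1.0, 1.0]), method="t_score")
        assert list(select_top_k(score, 2)) == [0, 1]

    def test_k_capped_at_d_with_warning(self):
        from cvleak.feature_selection import FeatureScore
        score = FeatureScore(scores=np.arange(10.0), method="t_score")
        with pytest.warns(UserWarning, match="capped"):
            idx = select_top_k(score, 64)
        assert len(idx) == 10

    def test_explicit_ranking_takes_precedence(self):
        from cvleak.feature_selection import FeatureScore
        score = FeatureScore(
            scores=np.array([3.0, 2.0, 1.0]),
            method="mrmr",
            selected_order=np.array([2, 0, 1]),
        )
        assert set(select_top_k(score, 2)) == {0, 2}


@pytest.mark.parametrize("method", sorted(ALL_SCORERS))
def test_permutation_equivariance(method, rng):
    """Permuting feature columns must permute every scorer's output identically."""
    n, d = 60, 12
    X = rng.normal(size=(n, d))
    y = np.array([0, 1] * (n // 2))
    X[:, 0] += 0.8 * y  # some signal so rankings are non-trivial
    X = (X - X.mean(0)) / X.std(0)
    perm = rng.permutation(d)
    base = ALL_SCORERS[method](X, y)
    permuted = ALL_SCORERS[method](X[:, perm], y)
    if base.selected_order is not None:
        inv = np.empty(d, dtype=int)
        inv[perm] = np.arange(d)
        assert list(permuted.selected_order) == [inv[f] for f in base.selected_order]
    else:
        np.testing.assert_allclose(permuted.scores, base.scores[perm], atol=1e-9)


@pytest.mark.parametrize("method", ["t_score", "mim"])
def test_null_top_rank_is_exchangeable(method, rng):
    """On null data every feature should be equally likely to rank first."""
    d, n, n_seeds = 8, 50, 200
    counts = np.zeros(d)
    for seed in range(n_seeds):
        local = np.random.default_rng(seed)
        X = local.normal(size=(n, d))
        y = np.array([0, 1] * (n // 2))
        cfg = SelectorConfig(method, 1)
        top = select_top_k(score_features(X, y, cfg, seed=seed), 1)[0]
        counts[top] += 1
    # binomial 99% bounds around n_seeds / d
    p = 1 / d
    sd = np.sqrt(n_seeds * p * (1 - p))
    assert np.all(np.abs(counts - n_seeds * p) < 2.58 * sd + 1)
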