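"""Classifier core: feature scoring, shrinkage LDA, AUC, grid search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mepdecode import defaults
from mepdecode.decoder import (FoldPlan, auc, chi2_feature_scores,
                               chi2_from_table, confusion, fit_lda,
                               grid_search, make_folds, mep_modulation,
                               rank_features)
from tests.conftest import gaussian_features


class TestChi2:
    def test_hand_built_table(self):
        """[[20,5],[5,20]] has chi-square statistic 18.0 at 1 df."""
        stat, p = chi2_from_table(np.array([[20, 5], [5, 20]]))
        assert stat == pytest.approx(18.0)
        assert p == pytest.approx(stats.chi2.sf(18.0, 1))

    def test_label_copy_feature_scores_highest(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 30)
        X = rng.standard_normal((60, 10))
        X[:, 4] = y  # two distinct values, perfectly dependent
        scores = chi2_feature_scores(X, y)
        assert np.argmax(scores) == 4

    def test_independent_feature_has_uniform_pvalues(self):
        """Permuted copies of the label are null features: mean p ~ 0.5."""
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 50)
        ps = []
        for _ in range(100):
            x = rng.permutation(rng.standard_normal(100))
            s = chi2_feature_scores(x[:, None], y)[0]
            ps.append(np.exp(-s))
        assert abs(np.mean(ps) - 0.5) < 0.1

    def test_degenerate_feature_scores_zero(self):
        y = np.repeat([0, 1], 5)
        X = np.ones((10, 1))
        assert chi2_feature_scores(X, y)[0] == 0.0

    def test_rank_ties_broken_by_index(self):
        order = rank_features(np.array([1.0, 3.0, 3.0, 0.5]))
        assert list(order) == [1, 2, 0, 3]


class TestLda:
    def test_lambda_one_is_nearest_class_mean(self):
        """At full shrinkage the weights align with m_high - m_low."""
        X, y, _ = gaussian_features(100, 8, coupled=[0, 3], effect=1.0, seed=2)
        model = fit_lda(X, y, 1.0)
        Z = (X - model.train_mean) / model.train_sd
        delta = Z[y == 1].mean(axis=0) - Z[y == 0].mean(axis=0)
        cos = model.weights @ delta / np.linalg.norm(model.weights) / np.linalg.norm(delta)
        assert cos > 0.999

    def test_separable_classes_reach_auc_one(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 100)
        X = rng.standard_normal((200, 5))
        X[y == 1] += 10.0  # means +-5 around the grand mean
        tr = np.r_[0:80, 100:180]
        te = np.r_[80:100, 180:200]
        model = fit_lda(X[tr], y[tr], 0.1)
        assert auc(model.decision_values(X[te]), y[te]) == 1.0

    def test_shuffled_labels_auc_centred_at_half(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((120, 6))
        aucs = []
        for _ in range(100):
            y = rng.permutation(np.repeat([0, 1], 60))
            model = fit_lda(X[:80], y[:80], 0.5)
            aucs.append(auc(model.decision_values(X[80:]), y[80:]))
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.zeros((4, 2)), np.zeros(4), 0.5)

    def test_lambda_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.zeros((4, 2)), np.array([0, 0, 1, 1]), 0.0)


class TestAuc:
    def test_perfect_ordering(self):
        assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_inverted_ordering(self):
        assert auc([4, 3, 2, 1], [0, 0, 1, 1]) == 0.0

    def test_ties_counted_half(self):
        # exhaustive pairs: highs {2,3} vs lows {1,2} -> (1 + 0.5 + 1 + 1)/4
        assert auc([1, 2, 2, 3], [0, 1, 0, 1]) == pytest.approx(0.875)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.tuples(st.integers(-5, 5), st.booleans()),
                    min_size=2, max_size=12))
    def test_matches_exhaustive_pair_counting(self, pairs):
        scores = np.array([s for s, _ in pairs], float)
        labels = np.array([int(b) for _, b in pairs])
        if labels.min() == labels.max():
            return
        total = wins = 0
        for sh in scores[labels == 1]:
            for sl in scores[labels == 0]:
                total += 1
                wins += (sh > sl) + 0.5 * (sh == sl)
        assert auc(scores, labels) == pytest.approx(wins / total)


class TestFolds:
    @pytest.mark.parametrize("n,k", [(50, 5), (53, 5), (30, 3)])
    def test_stratified_balance(self, n, k):
        rng = np.random.default_rng(n)
        y = rng.permutation((np.arange(n) < n // 2).astype(int))
        plan = make_folds(y, k=k, seed=1)
        for f in range(k):
            m = plan.assignments == f
            for c in (0, 1):
                per_fold = np.sum(y[m] == c)
                assert abs(per_fold - np.sum(y == c) / k) < 1

    def test_every_trial_in_one_fold(self):
        y = np.repeat([0, 1], 25)
        plan = make_folds(y, seed=0)
        assert sorted(np.concatenate([t for _, t in plan.split()])) == list(range(50))


class TestGridSearch:
    def test_configuration_count_is_grid_product(self, reduced_grids):
        n_grid, lam_grid = reduced_grids
        X, y, _ = gaussian_features(60, 168, coupled=[0], effect=1.0, seed=5)
        res = grid_search(X, y, n_feature_grid=n_grid, lambda_grid=lam_grid,
                          seed=0)
        assert res.n_configurations == len(n_grid) * len(lam_grid)
        assert res.auc_surface.shape == (len(n_grid), len(lam_grid))

    def test_determinism(self, reduced_grids):
        n_grid, lam_grid = reduced_grids
        X, y, _ = gaussian_features(60, 30, coupled=[1], effect=1.0, seed=6)
        a = grid_search(X, y, n_feature_grid=np.arange(1, 31, 4),
                        lambda_grid=lam_grid, seed=3)
        b = grid_search(X, y, n_feature_grid=np.arange(1, 31, 4),
                        lambda_grid=lam_grid, seed=3)
        assert np.array_equal(a.auc_surface, b.auc_surface)
        assert np.array_equal(a.per_trial_score, b.per_trial_score)
        assert (a.best_n_features, a.best_lambda) == (b.best_n_features, b.best_lambda)

    def test_best_is_surface_maximum_with_parsimony_tiebreak(self):
        X, y, _ = gaussian_features(50, 10, coupled=[0], effect=2.0, seed=7)
        res = grid_search(X, y, n_feature_grid=np.arange(1, 11),
                          lambda_grid=np.linspace(1e-10, 1, 5), seed=1)
        assert res.best_auc == res.auc_surface.max()
        ties = np.argwhere(res.auc_surface == res.best_auc)
        i, j = ties[0]  # row-major first: fewest features, then smallest lambda
        assert res.best_n_features == res.n_feature_grid[i]
        assert res.best_lambda == res.lambda_grid[j]

    def test_heldout_predictions_reproduce_best_auc(self):
        """Refit per-trial predictions must be consistent with the surface."""
        X, y, _ = gaussian_features(80, 20, coupled=[0, 1], effect=1.0, seed=8)
        res = grid_search(X, y, n_feature_grid=np.arange(1, 21, 3),
                          lambda_grid=np.linspace(1e-10, 1, 7), seed=2)
        per_fold = []
        for _, test in res.fold_plan.split():
            per_fold.append(auc(res.per_trial_score[test], y[test]))
        assert np.mean(per_fold) == pytest.approx(res.best_auc, abs=1e-12)

    def test_no_leakage_under_test_trial_deletion(self):
        """Removing a held-out trial changes neither that fold's feature
        ranking nor its trained weights."""
        X, y, _ = gaussian_features(60, 12, coupled=[2], effect=1.0, seed=9)
        plan = make_folds(y, k=5, seed=4)
        # fixed configuration so the trained model is directly comparable
        n_grid, lam_grid = np.array([5]), np.array([0.3])
        res = grid_search(X, y, fold_plan=plan,
                          n_feature_grid=n_grid, lambda_grid=lam_grid)
        # delete one trial of fold 0 (test trial for fold 0 models)
        victim = np.flatnonzero(plan.assignments == 0)[0]
        keep = np.arange(len(y)) != victim
        plan2 = FoldPlan(k=5, assignments=plan.assignments[keep], seed=4)
        res2 = grid_search(X[keep], y[keep], fold_plan=plan2,
                           n_feature_grid=n_grid, lambda_grid=lam_grid)
        assert np.array_equal(res.fold_rankings[0], res2.fold_rankings[0])
        np.testing.assert_allclose(res.fold_models[0].weights,
                                   res2.fold_models[0].weights)

    def test_single_class_fold_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 4))
        y = np.repeat([0, 1], 10)
        bad = FoldPlan(k=2, assignments=(np.arange(20) >= 10).astype(int), seed=0)
        with pytest.raises(ValueError):
            grid_search(X, y, fold_plan=bad, n_feature_grid=np.arange(1, 5),
                        lambda_grid=np.linspace(1e-10, 1, 3))


class TestSummaries:
    def test_confusion_perfect_and_inverted(self):
        y = np.array([0, 0, 1, 1])
        assert np.allclose(confusion(y, y), [[100, 0], [0, 100]])
        assert np.allclose(confusion(1 - y, y), [[0, 100], [100, 0]])

    def test_confusion_hand_count(self):
        """10 trials, 3 errors in the low class (n=5): low row = [40, 60]."""
        y = np.repeat([0, 1], 5)
        pred = y.copy()
        pred[:3] = 1
        c = confusion(pred, y)
        assert np.allclose(c[0], [40, 60])
        assert np.allclose(c[1], [0, 100])

    def test_modulation_equals_true_split_when_predictions_match(self):
        amps = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0, 0, 1, 1])
        mod = mep_modulation(y, amps, true_labels=y)
        assert mod["ratio"] == pytest.approx(3.5 / 1.5)
        assert mod["ratio"] == pytest.approx(mod["true_ratio"])

    def test_random_predictions_give_null_modulation(self):
        rng = np.random.default_rng(10)
        percents = []
        for _ in range(20):
            amps = rng.lognormal(6, 0.8, size=600)
            pred = rng.permutation(np.repeat([0, 1], 300))
            percents.append(mep_modulation(pred, amps)["percent"])
        assert abs(np.median(percents)) < 10

    def test_degenerate_predictions_rejected(self):
        with pytest.raises(ValueError):
            mep_modulation(np.ones(4, int), np.ones(4))
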