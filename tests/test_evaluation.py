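"""Permutation inference, generalization analyses, group statistics."""

import numpy as np
import pytest

from mepdecode import defaults
from mepdecode.containers import FeatureMatrix
from mepdecode.decoder import grid_search, make_folds
from mepdecode.evaluation import (classify_all_windows, cross_participant,
                                  fdr_bh, mann_whitney_u, permutation_test,
                                  spearman, temporal_generalization,
                                  trial_count_curve, wilcoxon_signed_rank)
from tests.conftest import gaussian_features

SMALL_N_GRID = np.array([1, 4, 8, 16])
SMALL_LAM_GRID = np.linspace(1e-10, 1, 5)


def _fm(values, window_id=5):
    desc = tuple(("ch%d" % i, "b") for i in range(values.shape[1]))
    return FeatureMatrix(values=values, descriptors=desc, window_id=window_id)


class TestPermutation:
    def test_zero_reps_rejected(self):
        X, y, _ = gaussian_features(40, 16, coupled=[0], effect=1.0, seed=0)
        with pytest.raises(ValueError):
            permutation_test(X, y, 0.6, reps=0)

    def test_few_reps_warns(self):
        X, y, _ = gaussian_features(40, 16, coupled=[0], effect=1.0, seed=0)
        with pytest.warns(UserWarning, match="unstable"):
            permutation_test(X, y, 0.6, reps=5,
                             n_feature_grid=SMALL_N_GRID,
                             lambda_grid=SMALL_LAM_GRID)

    def test_strong_coupling_is_significant(self):
        X, y, _ = gaussian_features(120, 16, coupled=[0, 1], effect=1.5, seed=1)
        res = grid_search(X, y, fold_plan=make_folds(y, seed=1),
                          n_feature_grid=SMALL_N_GRID,
                          lambda_grid=SMALL_LAM_GRID)
        null = permutation_test(X, y, res.best_auc, reps=99, seed=1,
                                n_feature_grid=SMALL_N_GRID,
                                lambda_grid=SMALL_LAM_GRID)
        assert null.significant
        assert null.threshold < res.best_auc

    def test_null_empirical_chance_above_half(self):
        """Optimization bias: the null mean sits above 0.5 (but below ~0.65)."""
        X, y, _ = gaussian_features(60, 16, coupled=[], effect=0.0, seed=2)
        null = permutation_test(X, y, 0.5, reps=60, seed=2,
                                n_feature_grid=SMALL_N_GRID,
                                lambda_grid=SMALL_LAM_GRID)
        assert 0.5 < null.empirical_chance < 0.7


class TestCrossParticipant:
    def _cohort(self, shared, n_p=3, seed=0):
        Xs, ys, results = [], [], []
        for i in range(n_p):
            coupled = [0, 1] if shared else [4 * i, 4 * i + 1]
            X, y, _ = gaussian_features(80, 16, coupled=coupled, effect=1.5,
                                        seed=seed + i)
            res = grid_search(X, y, fold_plan=make_folds(y, seed=i),
                              n_feature_grid=SMALL_N_GRID,
                              lambda_grid=SMALL_LAM_GRID)
            Xs.append(X)
            ys.append(y)
            results.append(res)
        return Xs, ys, results

    def test_diagonal_is_personalized_auc(self):
        Xs, ys, results = self._cohort(shared=True)
        gm = cross_participant(Xs, ys, results)
        for i, res in enumerate(results):
            assert gm.auc[i, i] == res.best_auc

    def test_shared_structure_transfers(self):
        Xs, ys, results = self._cohort(shared=True, seed=10)
        gm = cross_participant(Xs, ys, results)
        off = gm.auc[~np.eye(len(Xs), dtype=bool)]
        assert off.mean() > 0.55

    def test_disjoint_features_do_not_transfer(self):
        Xs, ys, results = self._cohort(shared=False, seed=20)
        gm = cross_participant(Xs, ys, results)
        off = gm.auc[~np.eye(len(Xs), dtype=bool)]
        assert 0.4 <= off.mean() <= 0.6

    def test_descriptor_mismatch_rejected(self):
        Xs, ys, results = self._cohort(shared=True)
        Xs[1] = Xs[1][:, :12]
        with pytest.raises(ValueError):
            cross_participant(Xs, ys, results)

    def test_single_participant_rejected(self):
        Xs, ys, results = self._cohort(shared=True)
        with pytest.raises(ValueError):
            cross_participant(Xs[:1], ys[:1], results[:1])


class TestTemporal:
    def test_self_generalization_is_exact(self):
        """Scoring the final window with the final-window models reproduces
        the personalized AUC bit-for-bit."""
        X, y, _ = gaussian_features(80, 16, coupled=[0], effect=1.2, seed=3)
        res = grid_search(X, y, fold_plan=make_folds(y, seed=3),
                          n_feature_grid=SMALL_N_GRID,
                          lambda_grid=SMALL_LAM_GRID)
        aucs = temporal_generalization(res, X, [_fm(X)], y)
        assert aucs[0] == res.best_auc

    def test_noise_windows_sit_at_chance(self):
        rng = np.random.default_rng(4)
        X, y, _ = gaussian_features(600, 16, coupled=[0, 1], effect=1.5, seed=4)
        res = grid_search(X, y, fold_plan=make_folds(y, seed=4),
                          n_feature_grid=SMALL_N_GRID,
                          lambda_grid=SMALL_LAM_GRID)
        noise = rng.standard_normal(X.shape)
        aucs = temporal_generalization(res, X, [_fm(noise, 0), _fm(X)], y)
        assert abs(aucs[0] - 0.5) < 0.05
        assert aucs[1] > 0.55

    def test_correlated_earlier_window_generalizes(self):
        """An earlier window whose features are a noisy copy of the final
        window stays above chance."""
        rng = np.random.default_rng(5)
        X, y, _ = gaussian_features(200, 16, coupled=[0, 1], effect=1.5, seed=5)
        res = grid_search(X, y, fold_plan=make_folds(y, seed=5),
                          n_feature_grid=SMALL_N_GRID,
                          lambda_grid=SMALL_LAM_GRID)
        earlier = 0.8 * X + 0.6 * rng.standard_normal(X.shape) * X.std(axis=0)
        aucs = temporal_generalization(res, X, [_fm(earlier, 4), _fm(X)], y)
        assert aucs[0] > 0.55

    def test_identical_windows_identical_aucs(self):
        X, y, _ = gaussian_features(60, 16, coupled=[0], effect=1.0, seed=6)
        fms = [_fm(X.copy(), w) for w in range(3)]
        results = classify_all_windows(fms, y, seed=7,
                                       n_feature_grid=SMALL_N_GRID,
                                       lambda_grid=SMALL_LAM_GRID)
        aucs = [r.best_auc for r in results]
        assert aucs[0] == aucs[1] == aucs[2]

    def test_trial_mismatch_rejected(self):
        X, y, _ = gaussian_features(60, 16, coupled=[0], effect=1.0, seed=6)
        with pytest.raises(ValueError):
            classify_all_windows([_fm(X[:-1])], y)


class TestTrialCountCurve:
    def test_fold_sizes_at_50_trials(self):
        X, y, _ = gaussian_features(50, 16, coupled=[0], effect=1.0, seed=8)
        amps = np.exp(np.random.default_rng(8).standard_normal(50))
        rows = trial_count_curve(X, y, amps, sizes=(50,), seed=8,
                                 n_feature_grid=SMALL_N_GRID,
                                 lambda_grid=SMALL_LAM_GRID)
        assert rows[0]["size"] == 50  # 5 folds of exactly 10 trials

    def test_oversize_requests_truncated_with_warning(self):
        X, y, _ = gaussian_features(60, 16, coupled=[0], effect=1.0, seed=9)
        amps = np.ones(60)
        with pytest.warns(UserWarning, match="truncated"):
            rows = trial_count_curve(X, y, amps, sizes=(50, 100, 150), seed=9,
                                     n_feature_grid=SMALL_N_GRID,
                                     lambda_grid=SMALL_LAM_GRID)
        assert [r["size"] for r in rows] == [50]

    def test_undersized_folds_rejected(self):
        X, y, _ = gaussian_features(60, 16, coupled=[0], effect=1.0, seed=9)
        with pytest.raises(ValueError):
            trial_count_curve(X, y, np.ones(60), sizes=(8,),
                              n_feature_grid=SMALL_N_GRID,
                              lambda_grid=SMALL_LAM_GRID)

    def test_stationary_coupling_flat_curve(self):
        X, y, _ = gaussian_features(450, 16, coupled=[0, 1], effect=1.5, seed=10)
        amps = np.ones(450)
        rows = trial_count_curve(X, y, amps, sizes=(50, 450), seed=10,
                                 n_feature_grid=SMALL_N_GRID,
                                 lambda_grid=SMALL_LAM_GRID)
        # no drift injected: small-N AUC within sampling noise of large-N
        assert abs(rows[0]["auc"] - rows[1]["auc"]) < 0.15

    def test_decaying_coupling_favours_early_trials(self):
        """Coupling that dies after trial 100 mirrors the fatigue account:
        the 50-trial dataset outperforms the 450-trial one."""
        rng = np.random.default_rng(11)
        e = rng.standard_normal(450)
        X = rng.standard_normal((450, 16))
        alive = np.arange(450) < 100
        for j in (0, 1):
            X[alive, j] += 2.0 * e[alive]
        y = (e > np.median(e)).astype(int)
        rows = trial_count_curve(X, y, np.ones(450), sizes=(50, 450), seed=11,
                                 n_feature_grid=SMALL_N_GRID,
                                 lambda_grid=SMALL_LAM_GRID)
        assert rows[0]["auc"] > rows[1]["auc"]


class TestGroupStats:
    def test_all_equal_pairs_give_p_one(self):
        stat, p = wilcoxon_signed_rank(np.full(10, 0.62), reference=0.62)
        assert p == 1.0

    def test_exact_right_tailed_signed_rank(self):
        """Values 1..20 vs 0: all ranks positive, exact p = 2^-20."""
        _, p = wilcoxon_signed_rank(np.arange(1, 21, dtype=float),
                                    reference=0.0, tail="greater")
        assert p == pytest.approx(2.0**-20)

    def test_bh_step_up_printed_example(self):
        reject, p_adj = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04, 0.05]),
                               alpha=0.05)
        assert reject.all()

    def test_bh_hand_computed_adjustment(self):
        # step-up by hand: p*(m/rank), enforced monotone from the largest
        p = np.array([0.005, 0.04, 0.03, 0.20])
        _, p_adj = fdr_bh(p)
        assert p_adj == pytest.approx([0.02, 0.053333333, 0.053333333, 0.20])

    def test_fdr_monotone_in_raw_p(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=40)
        _, p_adj = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)

    def test_mann_whitney_direction(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = a + 10
        _, p_less = mann_whitney_u(a, b, tail="less")
        _, p_greater = mann_whitney_u(a, b, tail="greater")
        assert p_less < 0.05 < p_greater

    def test_spearman_right_tailed(self):
        x = np.arange(20.0)
        rho, p = spearman(x, x**3, tail="greater")
        assert rho == pytest.approx(1.0)
        assert p < 1e-6
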