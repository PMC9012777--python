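"""Inference and generalization analyses on top of the personalized decoder.

Covers: permutation-based significance of the personalized AUC (the full
grid search re-run on shuffled labels), cross-participant generalization of
personalized classifiers, per-window classification and backwards temporal
generalization over the six pre-TMS windows, trial-count curves, and the
nonparametric group statistics (Wilcoxon signed rank, Mann-Whitney U,
Benjamini-Hochberg FDR, Spearman).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import defaults
from .containers import FeatureMatrix
from .decoder import (FoldPlan, GridSearchResult, auc, chi2_feature_scores,
                      fit_lda, grid_search, make_folds, mep_modulation,
                      rank_features)


# ---------------------------------------------------------------------------
# Permutation significance

@dataclass
class PermutationNull:
    """Null distribution of grid-search AUCs under shuffled labels."""

    null_aucs: np.ndarray
    threshold: float   # 95th percentile of the null
    true_auc: float
    significant: bool
    seed: int

    @property
    def empirical_chance(self) -> float:
        """Mean of the null distribution (the empirical chance level)."""
        return float(self.null_aucs.mean())


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    true_auc: float,
    reps: int = defaults.PERMUTATION_REPS,
    seed: int = 0,
    n_feature_grid: np.ndarray | None = None,
    lambda_grid: np.ndarray | None = None,
    k: int = defaults.K_FOLDS,
) -> PermutationNull:
    """Re-run the full cross-validated grid search on shuffled labels.

    Each rep shuffles the labels uniformly, re-stratifies the folds on the
    shuffled labels, and re-runs the complete search (including per-fold
    feature ranking); its best mean AUC is one null sample. Significance:
    ``true_auc`` above the 95th percentile of the null. Grid density and
    rep count are configurable for scaled-down runs.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if reps < 20:
        warnings.warn("fewer than 20 permutations: the 95th percentile "
                      "of the null is unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    for r in range(reps):
        y_perm = rng.permutation(y)
        fold_seed = int(rng.integers(2**31 - 1))
        res = grid_search(X, y_perm, fold_plan=make_folds(y_perm, k=k,
                                                          seed=fold_seed),
                          n_feature_grid=n_feature_grid,
                          lambda_grid=lambda_grid)
        null[r] = res.best_auc
    threshold = float(np.percentile(null, 95))
    return PermutationNull(null_aucs=null, threshold=threshold,
                           true_auc=float(true_auc),
                           significant=bool(true_auc > threshold), seed=seed)


# ---------------------------------------------------------------------------
# Cross-participant generalization

@dataclass
class GeneralizationMatrix:
    """Train-participant x test-participant AUC matrix.

    The diagonal holds the personalized (within-participant, cross-validated)
    AUCs; off-diagonal entries test a classifier trained on all trials of
    participant i on all trials of participant j.
    """

    auc: np.ndarray
    participants: tuple[str, ...]

    def offdiag_mean_per_train(self) -> np.ndarray:
        """Mean AUC over test participants, per training participant."""
        m = self.auc.copy()
        np.fill_diagonal(m, np.nan)
        return np.nanmean(m, axis=1)


def cross_participant(
    features_by_participant: list[np.ndarray],
    labels_by_participant: list[np.ndarray],
    personalized_results: list[GridSearchResult],
    participants: tuple[str, ...] | None = None,
) -> GeneralizationMatrix:
    """Generalization of each personalized classifier to every other participant.

    For training participant i, features are re-ranked on ALL of i's trials,
    an LDA with i's personalized best (n, λ) is fit on all of i's trials, and
    scored on all trials of each j != i. Train and test sets never share
    trials. The diagonal carries the personalized cross-validated AUCs.
    """
    n_p = len(features_by_participant)
    if n_p < 2:
        raise ValueError("cross-participant generalization needs >= 2 participants")
    if not (len(labels_by_participant) == len(personalized_results) == n_p):
        raise ValueError("per-participant inputs have mismatched lengths")
    p = features_by_participant[0].shape[1]
    for Xj in features_by_participant:
        if Xj.shape[1] != p:
            raise ValueError("feature descriptor ordering differs across participants")
    if participants is None:
        participants = tuple(f"P{i:02d}" for i in range(n_p))

    M = np.empty((n_p, n_p))
    for i in range(n_p):
        Xi, yi = features_by_participant[i], labels_by_participant[i]
        res = personalized_results[i]
        order = rank_features(chi2_feature_scores(Xi, yi))
        model = fit_lda(Xi, yi, res.best_lambda,
                        feature_indices=order[:res.best_n_features])
        M[i, i] = res.best_auc
        for j in range(n_p):
            if j == i:
                continue
            sc = model.decision_values(features_by_participant[j])
            M[i, j] = auc(sc, labels_by_participant[j])
    return GeneralizationMatrix(auc=M, participants=participants)


# ---------------------------------------------------------------------------
# Temporal analyses

def classify_all_windows(
    features_per_window: list[FeatureMatrix],
    y: np.ndarray,
    seed: int = 0,
    n_feature_grid: np.ndarray | None = None,
    lambda_grid: np.ndarray | None = None,
    k: int = defaults.K_FOLDS,
) -> list[GridSearchResult]:
    """Independent full grid search per pre-TMS window (shared trials)."""
    n = len(y)
    for fm in features_per_window:
        if fm.values.shape[0] != n:
            raise ValueError("feature matrices and labels disagree on trial count")
    out = []
    for fm in features_per_window:
        plan = make_folds(y, k=k, seed=seed)
        out.append(grid_search(fm.values, y, fold_plan=plan,
                               n_feature_grid=n_feature_grid,
                               lambda_grid=lambda_grid))
    return out


def temporal_generalization(
    final_result: GridSearchResult,
    final_features: np.ndarray,
    features_per_window: list[FeatureMatrix],
    y: np.ndarray,
) -> np.ndarray:
    """Backward generalization of the final-window classifier.

    Per fold, the model trained on the final window's training folds (at the
    personalized best configuration, with that fold's feature ranking) scores
    the held-out trials' features from each earlier window; per-window AUCs
    are averaged over folds. Scoring the final window itself reproduces the
    personalized AUC exactly.
    """
    plan = final_result.fold_plan
    for fm in features_per_window:
        if fm.values.shape[0] != len(y):
            raise ValueError("feature matrices and labels disagree on trial count")
    aucs = np.zeros(len(features_per_window))
    for f, (train, test) in enumerate(plan.split()):
        model = fit_lda(
            final_features[train], y[train], final_result.best_lambda,
            feature_indices=final_result.fold_rankings[f][:final_result.best_n_features],
        )
        for wi, fm in enumerate(features_per_window):
            aucs[wi] += auc(model.decision_values(fm.values[test]), y[test])
    return aucs / plan.k


# ---------------------------------------------------------------------------
# Trial-count curve

def trial_count_curve(
    X: np.ndarray,
    y: np.ndarray,
    amplitudes: np.ndarray,
    sizes: tuple[int, ...] = tuple(range(50, 451, 50)),
    seed: int = 0,
    n_feature_grid: np.ndarray | None = None,
    lambda_grid: np.ndarray | None = None,
    k: int = defaults.K_FOLDS,
) -> list[dict]:
    """Grid search on the first N trials (occurrence order) for each size N.

    Returns per-size dicts with the best AUC and the classifier-predicted
    MEP modulation. Sizes exceeding the available trial count are dropped
    with a warning; a size below 2k cannot populate stratified folds and
    raises.
    """
    n = len(y)
    usable = [s for s in sizes if s <= n]
    if len(usable) < len(sizes):
        warnings.warn(f"sizes truncated to {usable} ({n} trials available)",
                      stacklevel=2)
    out = []
    for s in usable:
        if s < 2 * k:
            raise ValueError(f"size {s} cannot fill {k} stratified folds")
        ys = y[:s]
        res = grid_search(X[:s], ys, fold_plan=make_folds(ys, k=k, seed=seed),
                          n_feature_grid=n_feature_grid,
                          lambda_grid=lambda_grid)
        try:
            mod = mep_modulation(res.per_trial_prediction, amplitudes[:s])
        except ValueError:
            mod = {"ratio": np.nan, "percent": np.nan}
        out.append({"size": s, "auc": res.best_auc,
                    "modulation_ratio": mod["ratio"],
                    "modulation_percent": mod["percent"],
                    "best_n_features": res.best_n_features,
                    "best_lambda": res.best_lambda})
    return out


# ---------------------------------------------------------------------------
# Group-level nonparametric statistics

def wilcoxon_signed_rank(values: np.ndarray,
                         reference: float | np.ndarray = 0.0,
                         tail: str = "two-sided") -> tuple[float, float]:
    """One-sample / paired Wilcoxon signed rank test.

    ``tail`` in {"two-sided", "greater", "less"} tests the location of
    values - reference against zero. Zero differences are discarded
    (classic convention); the exact distribution is used for n <= 25.
    """
    d = np.asarray(values, float) - reference
    d = d[d != 0]
    if len(d) == 0:
        return 0.0, 1.0  # no informative pairs
    if len(d) < 5:
        warnings.warn("n < 5: signed-rank p-values are coarse", stacklevel=2)
    method = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(d, alternative=tail, method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(a: np.ndarray, b: np.ndarray,
                   tail: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test of a vs b (independent samples)."""
    res = stats.mannwhitneyu(a, b, alternative=tail)
    return float(res.statistic), float(res.pvalue)


def fdr_bh(pvalues: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR. Returns (reject flags, adjusted p)."""
    reject, p_adj, _, _ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def spearman(a: np.ndarray, b: np.ndarray,
             tail: str = "greater") -> tuple[float, float]:
    """Spearman rank correlation (right-tailed by default)."""
    res = stats.spearmanr(a, b, alternative=tail)
    return float(res.statistic), float(res.pvalue)
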