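"""Personalized excitability-state classification.

The classifier is a shrinkage Linear Discriminant Analysis trained per
participant on band-power features, with two hyperparameters optimized by a
stratified 5-fold cross-validated grid search: the number of features kept
(features added in order of a chi-square importance score computed on the
training folds only) and the shrinkage intensity λ (100 values linearly
spaced in [1e-10, 1]). With the default 168 features this evaluates
168 x 100 = 16,800 cross-validated configurations.

Shrinkage semantics: the pooled within-class covariance S of the
standardized training features is regularized as

    S(λ) = (1 - λ) S + λ ν I,     ν = trace(S) / p,

so λ = 1 collapses to a (scaled) nearest-class-mean rule and λ -> 0
recovers plain LDA. The discriminant is w = S(λ)^{-1} (m_high - m_low) with
the decision threshold at the midpoint of the class means; decision values
above zero predict the high-excitability state.

For a fixed fold and feature count the whole λ grid is swept from one
eigendecomposition of S: S = U diag(d) U', so
S(λ)^{-1} δ = U diag(1/((1-λ)d + λν)) U' δ for every λ at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from . import defaults

_TINY_P = np.nextafter(0, 1)  # smallest positive subnormal; keeps -log(p) finite


# ---------------------------------------------------------------------------
# Fold plan

@dataclass
class FoldPlan:
    """Stratified assignment of trials to k cross-validation folds."""

    k: int
    assignments: np.ndarray
    seed: int

    def split(self):
        """Yield (train_idx, test_idx) per fold, in fold order."""
        for f in range(self.k):
            test = np.flatnonzero(self.assignments == f)
            train = np.flatnonzero(self.assignments != f)
            yield train, test


def make_folds(labels: np.ndarray, k: int = defaults.K_FOLDS,
               seed: int = 0) -> FoldPlan:
    """Stratified k-fold plan; per-fold class counts differ by <= 1."""
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), int)
    for f, (_, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[test] = f
    return FoldPlan(k=k, assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------
# Chi-square feature ranking

def chi2_from_table(table: np.ndarray) -> tuple[float, float]:
    """Chi-square test of independence on a contingency table.

    No continuity correction; zero-count rows/columns are dropped (the
    merged-empty-bin convention). Returns (statistic, p).
    """
    O = np.asarray(table, float)
    O = O[O.sum(axis=1) > 0][:, O.sum(axis=0) > 0]
    if O.shape[0] < 2 or O.shape[1] < 2:
        return 0.0, 1.0
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / O.sum()
    stat = float(((O - E) ** 2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return stat, float(stats.chi2.sf(stat, df))


def chi2_feature_scores(X: np.ndarray, y: np.ndarray,
                        n_bins: int = 10) -> np.ndarray:
    """Per-feature -log(p) of a binned chi-square independence test.

    Each continuous feature is discretized into ``n_bins`` equal-frequency
    bins (edges from the supplied data, i.e. the training folds), and tested
    for independence from the binary class. Empty bins (e.g. from duplicate
    quantile edges) are dropped before the test; degenerate features (a
    single occupied bin) score 0. Vectorized across features.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("need >= 2 trials of each class to rank features")
    n, p = X.shape
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.quantile(X, qs, axis=0)                      # (n_bins-1, p)
    # bin index = number of edges strictly below the value (duplicate edges
    # simply yield permanently-empty bins, dropped below)
    bins = (X[None, :, :] > edges[:, None, :]).sum(axis=0)  # (n, p)
    counts = np.zeros((p, n_bins, 2))
    feat_idx = np.broadcast_to(np.arange(p), (n, p))
    np.add.at(counts, (feat_idx, bins, (y == 1).astype(int)[:, None]), 1)

    row = counts.sum(axis=2)                                # (p, n_bins)
    col = counts.sum(axis=1)                                # (p, 2)
    occupied = row > 0
    n_rows = occupied.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        E = row[:, :, None] * col[:, None, :] / n
        cell = np.where(E > 0, (counts - E) ** 2 / E, 0.0)
    stat = cell.sum(axis=(1, 2))
    df = np.maximum(n_rows - 1, 1) * (np.sum(col > 0, axis=1) - 1)
    pvals = np.where(df > 0, stats.chi2.sf(stat, np.maximum(df, 1)), 1.0)
    pvals = np.where(n_rows < 2, 1.0, pvals)
    return -np.log(np.maximum(pvals, _TINY_P))


def rank_features(scores: np.ndarray) -> np.ndarray:
    """Feature order by descending score; ties by ascending feature index."""
    return np.argsort(-scores, kind="stable")


# ---------------------------------------------------------------------------
# Shrinkage LDA

@dataclass
class LdaModel:
    """A trained shrinkage-LDA discriminant over a feature subset."""

    weights: np.ndarray
    bias: float
    lam: float
    feature_indices: np.ndarray
    train_mean: np.ndarray
    train_sd: np.ndarray

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Signed distances from the class-midpoint hyperplane; > 0 = high."""
        Z = (X[:, self.feature_indices] - self.train_mean) / self.train_sd
        return Z @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_values(X) > 0).astype(int)


def _standardize_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def _pooled_cov(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(pooled within-class covariance, m_high - m_low) of standardized data."""
    m0 = Z[y == 0].mean(axis=0)
    m1 = Z[y == 1].mean(axis=0)
    C0 = Z[y == 0] - m0
    C1 = Z[y == 1] - m1
    S = (C0.T @ C0 + C1.T @ C1) / (len(y) - 2)
    return S, m1 - m0


def fit_lda(X: np.ndarray, y: np.ndarray, lam: float,
            feature_indices: np.ndarray | None = None) -> LdaModel:
    """Fit shrinkage LDA on (a feature subset of) the training data.

    Features are z-scored with training statistics; λ must be positive
    (the search grid starts at 1e-10, never exactly 0).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the training set")
    if not 0 < lam <= 1:
        raise ValueError("lambda must lie in (0, 1]")
    if feature_indices is None:
        feature_indices = np.arange(X.shape[1])
    Xs = X[:, feature_indices]
    mean, sd = _standardize_stats(Xs)
    Z = (Xs - mean) / sd
    S, delta = _pooled_cov(Z, y)
    p = S.shape[0]
    nu = np.trace(S) / p
    S_lam = (1 - lam) * S + lam * nu * np.eye(p)
    w = np.linalg.solve(S_lam, delta)
    m0 = Z[y == 0].mean(axis=0)
    m1 = Z[y == 1].mean(axis=0)
    bias = -float(w @ (m0 + m1) / 2)
    return LdaModel(weights=w, bias=bias, lam=lam,
                    feature_indices=np.asarray(feature_indices),
                    train_mean=mean, train_sd=sd)


# ---------------------------------------------------------------------------
# AUC

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(score_high > score_low), ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    r = stats.rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _auc_columns(score_matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """AUC per column of an (n_trials, n_models) score matrix.

    Ranks are computed by double argsort (fast path); columns containing
    tied scores fall back to average ranks so ties count 1/2.
    """
    S = np.asarray(score_matrix, float)
    n, L = S.shape
    n1 = int(np.sum(labels == 1))
    n0 = n - n1
    order = np.argsort(S, axis=0, kind="stable")
    cols = np.arange(L)
    r = np.empty((n, L))
    r[order, cols] = np.broadcast_to(np.arange(1.0, n + 1)[:, None], (n, L))
    sorted_S = S[order, cols]
    tied = (sorted_S[1:] == sorted_S[:-1]).any(axis=0)
    for j in np.flatnonzero(tied):
        r[:, j] = stats.rankdata(S[:, j])
    return (r[labels == 1].sum(axis=0) - n1 * (n1 + 1) / 2) / (n1 * n0)


# ---------------------------------------------------------------------------
# Grid search

@dataclass
class GridSearchResult:
    """Outcome of the cross-validated (feature count x λ) grid search."""

    auc_surface: np.ndarray
    n_feature_grid: np.ndarray
    lambda_grid: np.ndarray
    best_n_features: int
    best_lambda: float
    best_auc: float
    per_trial_prediction: np.ndarray
    per_trial_score: np.ndarray
    fold_plan: FoldPlan
    fold_rankings: np.ndarray  # (k, p) feature order per fold
    n_configurations: int
    fold_models: list[LdaModel] = field(default_factory=list, repr=False)


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    fold_plan: FoldPlan | None = None,
    n_feature_grid: np.ndarray | None = None,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    k: int = defaults.K_FOLDS,
) -> GridSearchResult:
    """Cross-validated search over (number of top-ranked features, λ).

    Per fold, features are ranked by chi-square score on the training folds
    only; for every grid point an LDA is trained on the top-n features of
    the training folds and scored on the held-out fold. Mean held-out AUC
    across folds fills the surface; the best configuration maximizes it
    (ties resolved toward fewer features, then smaller λ). Held-out
    predictions for every trial come from its own fold's model at the best
    configuration.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    p = X.shape[1]
    if fold_plan is None:
        fold_plan = make_folds(y, k=k, seed=seed)
    if n_feature_grid is None:
        n_feature_grid = defaults.feature_count_grid(p)
    if lambda_grid is None:
        lambda_grid = defaults.lambda_grid()
    n_feature_grid = np.asarray(n_feature_grid, int)
    lambda_grid = np.asarray(lambda_grid, float)
    if n_feature_grid.max() > p:
        raise ValueError("feature grid exceeds available features")

    surface = np.zeros((len(n_feature_grid), len(lambda_grid)))
    rankings = np.empty((fold_plan.k, p), int)
    lam = lambda_grid

    for f, (train, test) in enumerate(fold_plan.split()):
        y_tr, y_te = y[train], y[test]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            raise ValueError(f"fold {f} holds a single class; check stratification")
        order = rank_features(chi2_feature_scores(X[train], y_tr))
        rankings[f] = order
        mean, sd = _standardize_stats(X[train])
        Z_tr = ((X[train] - mean) / sd)[:, order]
        Z_te = ((X[test] - mean) / sd)[:, order]
        n_tr = len(train)
        m0 = Z_tr[y_tr == 0].mean(axis=0)
        m1 = Z_tr[y_tr == 1].mean(axis=0)
        delta = m1 - m0
        m_mid = (m0 + m1) / 2
        # class-centered data matrix: S[:n,:n] = C[:, :n].T C[:, :n]/(n_tr-2)
        C = Z_tr.copy()
        C[y_tr == 0] -= m0
        C[y_tr == 1] -= m1
        trace_cum = np.cumsum((C**2).sum(axis=0)) / (n_tr - 2)

        # dual-route feature counts (n > n_tr): spectrum of the
        # (n_tr x n_tr) Gram matrix, built incrementally and
        # eigendecomposed in one stacked call per fold
        dual_ns = [int(n) for n in n_feature_grid if n > n_tr]
        dual_eig: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        if dual_ns:
            grams = np.empty((len(dual_ns), n_tr, n_tr))
            gram = C[:, :dual_ns[0]] @ C[:, :dual_ns[0]].T
            grams[0] = gram
            for gi in range(1, len(dual_ns)):
                B = C[:, dual_ns[gi - 1]:dual_ns[gi]]
                gram += B @ B.T
                grams[gi] = gram
            mus, Us = np.linalg.eigh(grams)
            dual_eig = {n: (mus[gi], Us[gi]) for gi, n in enumerate(dual_ns)}

        for i, n in enumerate(n_feature_grid):
            nu = trace_cum[n - 1] / n
            dn = delta[:n]
            if n <= n_tr:
                d, V = np.linalg.eigh(C[:, :n].T @ C[:, :n] / (n_tr - 2))
                z = V.T @ dn
                denom = np.outer(d, 1 - lam) + nu * lam   # (r, L)
                W = V @ (z[:, None] / denom)
            else:
                mu, U = dual_eig[int(n)]
                pos = mu > mu[-1] * 1e-12
                mu, U = mu[pos], U[:, pos]
                d = mu / (n_tr - 2)
                # V = C_n^T U / sqrt(mu); stay in dual coordinates
                cd = C[:, :n] @ dn                        # (n_tr,)
                z = (U.T @ cd) / np.sqrt(mu)              # V^T dn
                denom = np.outer(d, 1 - lam) + nu * lam
                A = (U / np.sqrt(mu)) @ (z[:, None] / denom)
                W = C[:, :n].T @ A
                # null-space component of delta is shrunk by λν alone
                Vz = C[:, :n].T @ ((U / np.sqrt(mu)) @ z)
                W += np.outer(dn - Vz, 1.0 / (nu * lam))
            bias = -(m_mid[:n] @ W)
            scores = Z_te[:, :n] @ W + bias
            surface[i] += _auc_columns(scores, y_te)

    surface /= fold_plan.k
    flat_best = int(np.argmax(surface))  # first max: fewer features, smaller λ
    bi, bj = np.unravel_index(flat_best, surface.shape)
    best_n = int(n_feature_grid[bi])
    best_lam = float(lambda_grid[bj])

    per_score = np.empty(len(y))
    per_pred = np.empty(len(y), int)
    fold_models: list[LdaModel] = []
    for f, (train, test) in enumerate(fold_plan.split()):
        model = fit_lda(X[train], y[train], best_lam,
                        feature_indices=rankings[f][:best_n])
        fold_models.append(model)
        sc = model.decision_values(X[test])
        per_score[test] = sc
        per_pred[test] = (sc > 0).astype(int)

    return GridSearchResult(
        auc_surface=surface,
        n_feature_grid=n_feature_grid,
        lambda_grid=lambda_grid,
        best_n_features=best_n,
        best_lambda=best_lam,
        best_auc=float(surface[bi, bj]),
        per_trial_prediction=per_pred,
        per_trial_score=per_score,
        fold_plan=fold_plan,
        fold_rankings=rankings,
        n_configurations=int(len(n_feature_grid) * len(lambda_grid)),
        fold_models=fold_models,
    )


# ---------------------------------------------------------------------------
# Post-hoc summaries

def confusion(predictions: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """2x2 percentage confusion matrix; rows = true (low, high), each row
    normalized to 100, columns = predicted (low, high)."""
    out = np.zeros((2, 2))
    for t in (0, 1):
        m = labels == t
        if m.sum() == 0:
            continue
        out[t, 0] = 100 * np.sum(predictions[m] == 0) / m.sum()
        out[t, 1] = 100 * np.sum(predictions[m] == 1) / m.sum()
    return out


def mep_modulation(predictions: np.ndarray, amplitudes: np.ndarray,
                   true_labels: np.ndarray | None = None) -> dict:
    """MEP-amplitude modulation between predicted high and low states.

    ratio = mean amplitude (predicted high) / mean amplitude (predicted low);
    percent = (ratio - 1) * 100. If true labels are given, the true-split
    modulation (the attainable ceiling) is reported alongside.
    """
    predictions = np.asarray(predictions)
    amplitudes = np.asarray(amplitudes, float)
    hi, lo = amplitudes[predictions == 1], amplitudes[predictions == 0]
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("degenerate classifier: one predicted class is empty")
    ratio = float(hi.mean() / lo.mean())
    out = {"ratio": ratio, "percent": (ratio - 1) * 100}
    if true_labels is not None:
        true_labels = np.asarray(true_labels)
        t_ratio = float(amplitudes[true_labels == 1].mean()
                        / amplitudes[true_labels == 0].mean())
        out["true_ratio"] = t_ratio
        out["true_percent"] = (t_ratio - 1) * 100
    return out
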