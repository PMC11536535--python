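"""Multivariate group-structure analysis: PCA, PLS-DA and ROC separation.

PCA handles missing values natively through NIPALS (each component's score
and loading regressions skip missing cells); PLS-DA instead imputes missing
entries first with an EM-style iterative-PCA scheme and then fits a
2-component PLS on one-hot group membership.  Group separation is quantified
as the ROC AUC of each group's predicted response column against all other
samples, with a two-sided Wilcoxon rank-sum p-value on the same scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import roc_auc_score


@dataclass
class ScoresResult:
    """Component scores with (for PCA) explained-variance fractions."""

    scores: pd.DataFrame             # samples x components
    loadings: pd.DataFrame           # features x components
    explained_variance: np.ndarray | None
    groups: pd.Series | None = None


@dataclass
class GroupSeparation:
    group: str
    auc: float
    p_value: float
    n_in: int
    n_out: int


# ---------------------------------------------------------------------------
# PCA (NIPALS with missing support)
# ---------------------------------------------------------------------------

def _center_scale(X: np.ndarray) -> np.ndarray:
    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    return (X - mean) / sd


def run_pca(matrix: pd.DataFrame, n_components: int = 2,
            tol: float = 1e-9, max_iter: int = 1000) -> ScoresResult:
    """Centered, unit-scaled PCA via NIPALS, tolerating missing cells.

    On complete data this reproduces classical PCA (scores from the SVD of
    the standardized matrix) up to sign; sign indeterminacy is resolved by
    making each component's largest-magnitude loading positive.  Zero-
    variance features are dropped with a warning; requesting more components
    than the matrix rank truncates with a warning.
    """
    X = matrix.to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    sd = np.nanstd(X, axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = matrix.columns[~keep].tolist()
        warnings.warn(f"dropping {len(dropped)} zero-variance features: "
                      f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}")
    features = matrix.columns[keep]
    X = _center_scale(X[:, keep])
    n, p = X.shape
    rank = min(n - 1, p)
    if n_components > rank:
        warnings.warn(f"requested {n_components} components, rank allows "
                      f"{rank}; truncating")
        n_components = rank

    obs = ~np.isnan(X)
    Xw = np.where(obs, X, 0.0)
    total_ss = np.sum(Xw**2)

    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    ev = np.zeros(n_components)
    R, Rw = X.copy(), Xw.copy()
    for k in range(n_components):
        j0 = int(np.argmax(np.nansum(R**2, axis=0)))
        t = np.where(np.isnan(R[:, j0]), 0.0, R[:, j0])
        if np.allclose(t, 0):
            t = np.ones(n)
        for _ in range(max_iter):
            # loadings: per-feature regression of observed cells on t
            denom = obs.T @ (t**2)
            pvec = (Rw.T @ t) / np.where(denom > 0, denom, 1.0)
            norm = np.linalg.norm(pvec)
            if norm == 0:
                break
            pvec /= norm
            denom_t = obs @ (pvec**2)
            t_new = (Rw @ pvec) / np.where(denom_t > 0, denom_t, 1.0)
            if np.linalg.norm(t_new - t) < tol * max(np.linalg.norm(t_new), 1.0):
                t = t_new
                break
            t = t_new
        if np.abs(pvec[np.argmax(np.abs(pvec))]) != pvec[np.argmax(np.abs(pvec))]:
            pvec, t = -pvec, -t
        T[:, k], P[:, k] = t, pvec
        ev[k] = np.sum(t**2)
        R = R - np.outer(t, pvec)
        Rw = np.where(obs, R, 0.0)

    order = np.argsort(-ev)
    T, P, ev = T[:, order], P[:, order], ev[order]
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return ScoresResult(
        scores=pd.DataFrame(T, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(P, index=features, columns=comp_names),
        explained_variance=ev / total_ss)


# ---------------------------------------------------------------------------
# iterative-PCA imputation
# ---------------------------------------------------------------------------

def impute_iterative_pca(matrix: pd.DataFrame, n_components: int = 2,
                         tol: float = 1e-6, max_iter: int = 200) -> pd.DataFrame:
    """EM-style imputation: alternate rank-k reconstruction and refill.

    Missing cells start at the feature mean; each iteration takes the rank-k
    truncated SVD of the column-centered completed matrix, reconstructs, and
    overwrites only the missing cells, until the largest change falls below
    ``tol``.  Complete matrices are returned unchanged (bit-identical).
    """
    X = matrix.to_numpy(float).copy()
    miss = np.isnan(X)
    if not miss.any():
        return matrix.copy()
    col_mean = np.nanmean(X, axis=0)
    X[miss] = np.take(col_mean, np.nonzero(miss)[1])
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        u, s, vt = np.linalg.svd(X - mu, full_matrices=False)
        recon = (u[:, :k] * s[:k]) @ vt[:k] + mu
        delta = np.max(np.abs(X[miss] - recon[miss]))
        X[miss] = recon[miss]
        if delta < tol:
            break
    return pd.DataFrame(X, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# PLS-DA with per-group ROC
# ---------------------------------------------------------------------------

def plsda_with_roc(matrix: pd.DataFrame, design: pd.DataFrame,
                   n_components: int = 2,
                   ) -> tuple[ScoresResult, list[GroupSeparation]]:
    """2-component PLS-DA on one-hot groups, with group-vs-rest AUC.

    Missing cells are imputed by :func:`impute_iterative_pca`; features are
    centered and unit-scaled inside the PLS fit.  The predicted score for
    group *g* is the fitted response column for *g*; its ROC curve against
    all other samples gives the AUC (oriented so AUC >= 0.5) and a two-sided
    Wilcoxon rank-sum test on the same scores gives the p-value.  Groups
    with a single sample are excluded from ROC with a warning.
    """
    groups = design.loc[matrix.index, "group"]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("PLS-DA needs at least 2 groups")

    X = impute_iterative_pca(matrix, n_components=n_components)
    zero_var = X.std(ddof=0) == 0
    X = X.loc[:, ~zero_var]
    Y = pd.get_dummies(groups).astype(float)[sorted(pd.unique(groups))]

    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(X.to_numpy(), Y.to_numpy())
    pred = pd.DataFrame(pls.predict(X.to_numpy()), index=X.index,
                        columns=Y.columns)
    comp_names = [f"LV{k + 1}" for k in range(n_components)]
    scores = ScoresResult(
        scores=pd.DataFrame(pls.x_scores_, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(pls.x_loadings_, index=X.columns,
                              columns=comp_names),
        explained_variance=None, groups=groups)

    separations: list[GroupSeparation] = []
    for g in levels:
        mask = (groups == g).to_numpy()
        if mask.sum() < 2:
            warnings.warn(f"group {g!r} has a single sample; excluded from ROC")
            continue
        score = pred[g].to_numpy()
        auc = roc_auc_score(mask.astype(int), score)
        auc = max(auc, 1 - auc)
        stat = stats.mannwhitneyu(score[mask], score[~mask],
                                  alternative="two-sided")
        separations.append(GroupSeparation(
            group=g, auc=float(auc), p_value=float(stat.pvalue),
            n_in=int(mask.sum()), n_out=int((~mask).sum())))
    return scores, separations
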