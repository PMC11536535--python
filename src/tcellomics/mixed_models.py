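"""Per-metabolite univariate inference with model selection.

For each metabolite the normalized log10 response is modelled with the two
crossed biological factors CELL (naive vs antigen-specific line) and
TREATMENT (vehicle vs pantethine) plus their interaction.  Incubation TIME
(6h/12h) enters only as a random intercept; the competing model drops the
random term entirely (fixed-effects-only generalized least squares, which
with homoscedastic errors is ordinary least squares).  Both models are fit
by maximum likelihood so their AICs and log-likelihoods are comparable, the
lower-AIC model wins (ties go to the simpler fixed-only model), and a
likelihood-ratio test for the variance component uses the boundary-corrected
50:50 mixture of chi-square 0 and 1 by default.

Contrasts are formed on the estimated marginal means of the four CELL x
TREATMENT cells (averaged over TIME, which carries no fixed effect): the
three comparisons of interest are PLP.CTRL - Naive.CTRL (cell-type shift at
baseline), PLP.PTTH - PLP.CTRL (treatment effect in the autoreactive line)
and Naive.PTTH - Naive.CTRL (treatment effect at rest).  Raw p-values are
Benjamini–Hochberg adjusted across features separately within each
comparison.

Metabolites graded usable only in some groups are fitted on those groups
with factors that become constant dropped from the design; contrasts whose
cells are not all usable are reported as missing and excluded from that
comparison's FDR family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import Grade, MissingnessGrade

CONTRASTS = {
    "PLP.CTRL-Naive.CTRL": (("PLP", "CTRL"), ("Naive", "CTRL")),
    "PLP.PTTH-PLP.CTRL": (("PLP", "PTTH"), ("PLP", "CTRL")),
    "Naive.PTTH-Naive.CTRL": (("Naive", "PTTH"), ("Naive", "CTRL")),
}

_VAR_FLOOR = 1e-12


@dataclass
class ModelComparison:
    feature: str
    aic_lmm: float
    aic_gls: float
    loglik_lmm: float
    loglik_gls: float
    lrt_stat: float
    lrt_p: float
    chosen: str                  # "LMM" | "GLS"
    converged: bool
    note: str = ""


@dataclass
class FeatureFit:
    """A fitted feature: fixed-effect estimates and their covariance."""

    feature: str
    comparison: ModelComparison
    params: pd.Series | None
    cov: pd.DataFrame | None
    df_resid: float
    design_cols: list[str]
    usable_groups: list[str] | None   # None = all four
    degenerate: bool = False


def _design_matrix(design: pd.DataFrame) -> pd.DataFrame:
    """Treatment-coded CELL*TREATMENT design (reference Naive/CTRL).

    Columns that are constant on the given samples (e.g. when a grade
    restricts to groups where one factor does not vary) are dropped.
    """
    X = pd.DataFrame(index=design.index)
    X["Intercept"] = 1.0
    X["CELL[PLP]"] = (design["CELL"] == "PLP").astype(float)
    X["TREAT[PTTH]"] = (design["TREATMENT"] == "PTTH").astype(float)
    X["CELL[PLP]:TREAT[PTTH]"] = X["CELL[PLP]"] * X["TREAT[PTTH]"]
    keep = ["Intercept"] + [c for c in X.columns[1:] if X[c].nunique() > 1]
    return X[keep]


def _cell_mean_row(cols: list[str], cell: str, trt: str) -> np.ndarray:
    """Row vector giving the marginal mean of one CELL x TREATMENT cell."""
    row = np.zeros(len(cols))
    for i, c in enumerate(cols):
        if c == "Intercept":
            row[i] = 1.0
        elif c == "CELL[PLP]":
            row[i] = float(cell == "PLP")
        elif c == "TREAT[PTTH]":
            row[i] = float(trt == "PTTH")
        elif c == "CELL[PLP]:TREAT[PTTH]":
            row[i] = float(cell == "PLP" and trt == "PTTH")
    return row


def _fit_one(y: pd.Series, design: pd.DataFrame, feature: str,
             lrt_mixture: bool = True) -> FeatureFit:
    X = _design_matrix(design)
    yv = y.to_numpy(float)
    n, p = X.shape

    if np.var(yv) < _VAR_FLOOR or n <= p:
        comp = ModelComparison(feature, np.nan, np.nan, np.nan, np.nan,
                               0.0, 1.0, "GLS", converged=False,
                               note="degenerate (constant response or n<=p)")
        return FeatureFit(feature, comp, None, None, max(n - p, 1),
                          list(X.columns), None, degenerate=True)

    ols = sm.OLS(yv, X.to_numpy()).fit()
    ll_gls = ols.llf
    aic_gls = ols.aic

    lmm_ok, ll_lmm, aic_lmm = False, np.nan, np.nan
    lmm_res = None
    if design["TIME"].nunique() > 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lmm = sm.MixedLM(yv, X, groups=design["TIME"].to_numpy())
                lmm_res = lmm.fit(reml=False, method=["lbfgs", "powell"])
            if np.isfinite(lmm_res.llf):
                # +1 parameter for the variance component vs the plain AIC
                ll_lmm = float(lmm_res.llf)
                aic_lmm = float(-2 * ll_lmm + 2 * (p + 2))
                lmm_ok = bool(lmm_res.converged)
        except Exception:
            lmm_ok = False

    if lmm_ok:
        lrt = max(0.0, 2 * (ll_lmm - ll_gls))
        if lrt_mixture:
            lrt_p = 1.0 if lrt == 0 else 0.5 * stats.chi2.sf(lrt, 1)
        else:
            lrt_p = stats.chi2.sf(lrt, 1) if lrt > 0 else 1.0
        chosen = "LMM" if aic_lmm < aic_gls else "GLS"
    else:
        lrt, lrt_p, chosen = np.nan, np.nan, "GLS"

    comp = ModelComparison(feature, aic_lmm, aic_gls, ll_lmm, ll_gls,
                           lrt, lrt_p if lmm_ok else 1.0, chosen,
                           converged=True,
                           note="" if lmm_ok else "LMM not converged")
    if chosen == "LMM":
        params = pd.Series(lmm_res.fe_params, index=X.columns)
        cov = pd.DataFrame(
            np.asarray(lmm_res.cov_params())[:p, :p],
            index=X.columns, columns=X.columns)
        df_resid = n - p - 1
    else:
        params = pd.Series(ols.params, index=X.columns)
        cov = pd.DataFrame(ols.cov_params(), index=X.columns, columns=X.columns)
        df_resid = n - p
    return FeatureFit(feature, comp, params, cov, max(df_resid, 1),
                      list(X.columns), None)


def fit_and_compare_models(normalized: pd.DataFrame, design: pd.DataFrame,
                           grades: MissingnessGrade | None = None,
                           lrt_mixture: bool = True) -> list[FeatureFit]:
    """Fit LMM and GLS per feature and pick by AIC.

    Features graded ``EXCLUDED`` are skipped; ``UVA_only`` features are fit
    on their usable groups with constant factors dropped.  Missing responses
    are dropped row-wise per feature.
    """
    fits: list[FeatureFit] = []
    for feat in normalized.columns:
        usable: list[str] | None = None
        if grades is not None:
            grade = grades.table.loc[feat, "grade"]
            if grade == Grade.EXCLUDED:
                continue
            if grade == Grade.UVA_ONLY:
                usable = grades.usable_groups(feat)
        y = normalized[feat]
        sub = design.loc[y.index]
        if usable is not None:
            keep = sub["group"].isin(usable)
            y, sub = y[keep], sub[keep]
        ok = y.notna()
        y, sub = y[ok], sub[ok]
        if len(y) < 3:
            comp = ModelComparison(feat, np.nan, np.nan, np.nan, np.nan,
                                   0.0, 1.0, "GLS", converged=False,
                                   note="too few observations")
            fits.append(FeatureFit(feat, comp, None, None, 1, [], usable,
                                   degenerate=True))
            continue
        fit = _fit_one(y, sub, feat, lrt_mixture=lrt_mixture)
        fit.usable_groups = usable
        fits.append(fit)
    return fits


# ---------------------------------------------------------------------------
# contrasts + FDR
# ---------------------------------------------------------------------------

def contrasts_with_fdr(fits: list[FeatureFit],
                       comparisons: dict | None = None) -> pd.DataFrame:
    """Marginal-mean contrasts with per-comparison Benjamini–Hochberg FDR.

    Returns a tidy frame: feature, comparison, estimate, se, p, p_adj,
    direction, chosen model, convergence flag.  Contrasts not estimable for
    a feature (unusable groups or degenerate fit from constant data) carry
    NaN estimates: degenerate-but-complete features enter the family with
    estimate 0 / p 1 (no evidence), truly inestimable ones are excluded
    from the FDR family.
    """
    comparisons = comparisons or CONTRASTS
    rows = []
    for fit in fits:
        for name, (cell_a, cell_b) in comparisons.items():
            estimable = True
            if fit.usable_groups is not None:
                need = {f"{c}/{t}" for c, t in (cell_a, cell_b)}
                estimable = need <= set(fit.usable_groups)
            if not estimable:
                rows.append({"feature": fit.feature, "comparison": name,
                             "estimate": np.nan, "se": np.nan, "p": np.nan,
                             "in_family": False, "chosen": fit.comparison.chosen,
                             "converged": fit.comparison.converged})
                continue
            if fit.degenerate or fit.params is None:
                rows.append({"feature": fit.feature, "comparison": name,
                             "estimate": 0.0, "se": np.nan, "p": 1.0,
                             "in_family": True, "chosen": fit.comparison.chosen,
                             "converged": fit.comparison.converged})
                continue
            cols = fit.design_cols
            L = (_cell_mean_row(cols, *cell_a) - _cell_mean_row(cols, *cell_b))
            est = float(L @ fit.params.to_numpy())
            var = float(L @ fit.cov.to_numpy() @ L)
            if var <= 0 or not np.isfinite(var):
                se, p = np.nan, 1.0
            else:
                se = np.sqrt(var)
                tval = est / se
                p = float(2 * stats.t.sf(abs(tval), fit.df_resid))
            rows.append({"feature": fit.feature, "comparison": name,
                         "estimate": est, "se": se, "p": p, "in_family": True,
                         "chosen": fit.comparison.chosen,
                         "converged": fit.comparison.converged})
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    for name in comparisons:
        fam = (table["comparison"] == name) & table["in_family"] & table["p"].notna()
        if fam.any():
            table.loc[fam, "p_adj"] = multipletests(
                table.loc[fam, "p"].to_numpy(), method="fdr_bh")[1]
    table["direction"] = np.sign(table["estimate"]).map(
        {1.0: "up", -1.0: "down", 0.0: "none"}).fillna("none")
    return table


def comparison_table(fits: list[FeatureFit]) -> pd.DataFrame:
    """Tidy per-feature model-selection table (AIC, logLik, LRT, choice)."""
    return pd.DataFrame([{
        "feature": f.feature,
        "aic_lmm": f.comparison.aic_lmm, "aic_gls": f.comparison.aic_gls,
        "loglik_lmm": f.comparison.loglik_lmm,
        "loglik_gls": f.comparison.loglik_gls,
        "lrt_stat": f.comparison.lrt_stat, "lrt_p": f.comparison.lrt_p,
        "chosen": f.comparison.chosen, "converged": f.comparison.converged,
        "note": f.comparison.note,
    } for f in fits]).set_index("feature")
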