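"""Metabolomics preprocessing: missingness grading, normalization, QC.

The preprocessing chain mirrors standard practice for semi-quantitative
metabolomics panels with substantial missingness:

1. grade each metabolite by its per-group missing fraction — complete enough
   everywhere for multivariate work (``MVA_UVA``), absent in specific groups
   but usable univariately elsewhere (``UVA_only``), or excluded;
2. correct for per-sample loading (cell-number) differences by dividing each
   sample by the median of its 0–1-scaled MVA metabolites, then log10;
3. run distributional checks (one-sample Kolmogorov–Smirnov against a fitted
   normal, Brown–Forsythe median-centred Levene across groups) and flag
   sample-level outliers by median, protein content and PCA position.

QC only reports — nothing is dropped unless the caller explicitly excludes
flagged samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats


class Grade(str, Enum):
    MVA_UVA = "MVA_UVA"
    UVA_ONLY = "UVA_only"
    EXCLUDED = "EXCLUDED"


@dataclass
class MissingnessGrade:
    """Per-feature missingness grading.

    ``table`` holds one row per feature: the missing fraction per group, the
    grade, and (for UVA_only features) the semicolon-joined usable groups.
    """

    table: pd.DataFrame
    threshold: float
    mnar_threshold: float

    @property
    def mva_features(self) -> list[str]:
        return self.table.index[self.table["grade"] == Grade.MVA_UVA].tolist()

    @property
    def uva_only_features(self) -> list[str]:
        return self.table.index[self.table["grade"] == Grade.UVA_ONLY].tolist()

    @property
    def excluded_features(self) -> list[str]:
        return self.table.index[self.table["grade"] == Grade.EXCLUDED].tolist()

    def usable_groups(self, feature: str) -> list[str]:
        val = self.table.loc[feature, "groups_usable"]
        return val.split(";") if val else []


def grade_missingness(matrix: pd.DataFrame, design: pd.DataFrame,
                      threshold: float = 0.30,
                      mnar_threshold: float = 0.90) -> MissingnessGrade:
    """Partition features by per-group missingness.

    * ``MVA_UVA``: missing fraction < ``threshold`` in every group;
    * ``UVA_only``: missing fraction >= ``mnar_threshold`` in at least one
      group (group-wise absence, i.e. not missing at random) while the
      remaining groups stay below ``threshold``; those remaining groups are
      recorded as usable;
    * ``EXCLUDED``: everything else.

    The three grades are mutually exclusive and exhaustive.
    """
    if not 0 < threshold < 1 or not 0 < mnar_threshold <= 1:
        raise ValueError("thresholds must lie in (0, 1)")
    groups = design.loc[matrix.index, "group"]
    counts = groups.value_counts()
    levels = (list(groups.cat.categories)
              if isinstance(groups.dtype, pd.CategoricalDtype)
              else list(pd.unique(groups)))
    empty = [g for g in levels if counts.get(g, 0) == 0]
    if empty or len(counts) == 0:
        raise ValueError(f"empty group(s): {empty or 'no groups at all'}")

    miss = matrix.isna().groupby(groups, observed=True).mean()  # groups x features
    rows = []
    for feat in matrix.columns:
        frac = miss[feat]
        if (frac < threshold).all():
            grade, usable = Grade.MVA_UVA, ""
        else:
            absent = frac.index[frac >= mnar_threshold]
            present = frac.index[frac < threshold]
            if len(absent) > 0 and len(absent) + len(present) == len(frac):
                grade, usable = Grade.UVA_ONLY, ";".join(sorted(present))
            else:
                grade, usable = Grade.EXCLUDED, ""
        rows.append({"feature": feat, "grade": grade, "groups_usable": usable,
                     **{f"miss_{g}": frac[g] for g in frac.index}})
    table = pd.DataFrame(rows).set_index("feature")
    return MissingnessGrade(table=table, threshold=threshold,
                            mnar_threshold=mnar_threshold)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_and_transform(matrix: pd.DataFrame,
                            mva_features: list[str] | set[str],
                            ) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-scaled-MVA normalization followed by log10.

    Each MVA feature is min–max scaled to [0, 1] across samples (non-missing
    values only); a per-sample factor is the median of that sample's scaled
    MVA values; every raw intensity is divided by its sample's factor and the
    result log10-transformed.  Missing stays missing.

    Degenerate factors (median 0, e.g. on tiny toy inputs where min–max
    scaling zeroes a whole row) fall back to the sample's mean scaled value;
    a still-zero factor is an error.

    Returns (normalized log10 matrix, per-sample factors).
    """
    mva = sorted(set(mva_features))
    missing = [f for f in mva if f not in matrix.columns]
    if missing:
        raise ValueError(f"MVA features not in matrix: {missing}")
    sub = matrix[mva].astype(float)
    if sub.notna().sum(axis=1).eq(0).any():
        bad = sub.index[sub.notna().sum(axis=1) == 0].tolist()
        raise ValueError(f"samples with all-missing MVA features: {bad}")

    lo, hi = sub.min(axis=0), sub.max(axis=0)
    span = (hi - lo).replace(0, np.nan)
    scaled = (sub - lo) / span
    # constant features scale to 0.5 by convention (no between-sample signal)
    constant = hi.index[(hi == lo)]
    for col in constant:
        scaled.loc[sub[col].notna(), col] = 0.5

    factors = scaled.median(axis=1, skipna=True)
    degenerate = factors <= 0
    factors[degenerate] = scaled.loc[degenerate].mean(axis=1, skipna=True)
    if (factors <= 0).any():
        bad = factors.index[factors <= 0].tolist()
        raise ValueError(f"non-positive normalization factor for samples: {bad}")

    normalized = np.log10(matrix.astype(float).div(factors, axis=0))
    return normalized, factors


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-feature distribution checks and per-sample outlier flags."""

    feature_tests: pd.DataFrame     # ks_stat, ks_p, bf_stat, bf_p, skipped
    sample_flags: pd.DataFrame      # median_outlier, protein_outlier, pca_outlier
    flagged_samples: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_features_tested": int((~self.feature_tests["skipped"]).sum()),
            "n_features_skipped": int(self.feature_tests["skipped"].sum()),
            "frac_ks_normal": float(
                (self.feature_tests["ks_p"] > 0.05).mean()),
            "frac_bf_homoscedastic": float(
                (self.feature_tests["bf_p"] > 0.05).mean()),
            "flagged_samples": list(self.flagged_samples),
            "sample_flags": self.sample_flags.astype(bool).to_dict("index"),
        }


def _mad_flags(values: pd.Series, k: float) -> pd.Series:
    """Flag entries outside median +/- k * MAD (scaled MAD, consistent SD)."""
    med = values.median()
    mad = stats.median_abs_deviation(values.dropna(), scale="normal")
    if mad == 0 or np.isnan(mad):
        return pd.Series(False, index=values.index)
    return (values - med).abs() > k * mad


def qc_report(normalized: pd.DataFrame, design: pd.DataFrame,
              protein_content: pd.Series | None = None,
              k_mad: float = 3.0) -> QCReport:
    """Distributional QC and sample outlier screen on the normalized matrix.

    Features with fewer than 3 non-missing values are skipped and recorded.
    The PCA screen imputes missing values with feature means, runs a 2-
    component PCA on the standardized matrix and flags samples whose distance
    from the score centroid exceeds ``k_mad`` scaled MADs.
    """
    groups = design.loc[normalized.index, "group"]
    rows = []
    for feat in normalized.columns:
        x = normalized[feat].dropna()
        if len(x) < 3 or x.std(ddof=1) == 0:
            rows.append({"feature": feat, "ks_stat": np.nan, "ks_p": np.nan,
                         "bf_stat": np.nan, "bf_p": np.nan, "skipped": True})
            continue
        ks_stat, ks_p = stats.kstest(
            x, "norm", args=(x.mean(), x.std(ddof=1)))
        by_group = [normalized.loc[groups == g, feat].dropna().to_numpy()
                    for g in groups.unique()]
        by_group = [v for v in by_group if len(v) >= 2]
        if len(by_group) >= 2:
            bf_stat, bf_p = stats.levene(*by_group, center="median")
        else:
            bf_stat, bf_p = np.nan, np.nan
        rows.append({"feature": feat, "ks_stat": ks_stat, "ks_p": ks_p,
                     "bf_stat": bf_stat, "bf_p": bf_p, "skipped": False})
    feature_tests = pd.DataFrame(rows).set_index("feature")

    sample_median = normalized.median(axis=1, skipna=True)
    flags = pd.DataFrame(index=normalized.index)
    flags["median_outlier"] = _mad_flags(sample_median, k_mad)
    if protein_content is not None:
        pc = pd.Series(protein_content).reindex(normalized.index)
        flags["protein_outlier"] = _mad_flags(pc, k_mad)
    else:
        flags["protein_outlier"] = False

    filled = normalized.apply(lambda c: c.fillna(c.mean()), axis=0)
    filled = filled.loc[:, filled.std(ddof=0) > 0]
    z = (filled - filled.mean()) / filled.std(ddof=0)
    u, s, _ = np.linalg.svd(z.to_numpy(), full_matrices=False)
    scores = u[:, :2] * s[:2]
    dist = pd.Series(np.linalg.norm(scores - scores.mean(axis=0), axis=1),
                     index=normalized.index)
    flags["pca_outlier"] = _mad_flags(dist, k_mad)

    flagged = flags.index[flags.any(axis=1)].tolist()
    return QCReport(feature_tests=feature_tests, sample_flags=flags,
                    flagged_samples=flagged)
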