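"""Antibody-microarray differential analysis via Z scores and Z ratios.

Background-corrected spot intensities are log2-transformed and standardized
within each array (sample): z = (log2 x - mean over all spots) / SD over all
spots.  Duplicate arrays of the same condition are averaged at the Z level.
The per-protein difference of condition-mean Z scores, divided by the SD of
all proteins' differences, is the Z ratio; |Z ratio| >= 1.1 is the
conventional significance call for this platform.  By construction the
Z-ratio vector has SD exactly 1 across proteins, which is asserted after
every run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_CUTOFF = 1.1


@dataclass
class ZScoreMatrix:
    """Per-sample Z scores of log2 spot intensities plus condition labels."""

    z: pd.DataFrame              # samples x proteins
    conditions: pd.Series        # sample -> condition


def compute_zscores(matrix: pd.DataFrame, design: pd.DataFrame,
                    ddof: int = 1) -> ZScoreMatrix:
    """Standardize log2 intensities within each sample.

    ``ddof=1`` (sample SD) is the default; ``ddof=0`` gives the population
    convention.  Zero or negative intensities and zero within-sample SD are
    errors — they indicate a broken input, not a statistical edge case.
    """
    vals = matrix.to_numpy(float)
    bad = np.argwhere(~np.isnan(vals) & (vals <= 0))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"non-positive intensity at sample {matrix.index[i]!r}, "
            f"spot {matrix.columns[j]!r}")
    log2 = np.log2(vals)
    mean = np.nanmean(log2, axis=1, keepdims=True)
    sd = np.nanstd(log2, axis=1, ddof=ddof, keepdims=True)
    flat = np.argwhere(sd.ravel() == 0)
    if len(flat):
        raise ValueError(
            f"zero within-sample SD for sample {matrix.index[flat[0][0]]!r}")
    z = pd.DataFrame((log2 - mean) / sd, index=matrix.index,
                     columns=matrix.columns)
    conditions = design.loc[matrix.index, "condition"]
    return ZScoreMatrix(z=z, conditions=conditions)


def compute_zratios(zmat: ZScoreMatrix, condition_a: str, condition_b: str,
                    cutoff: float = DEFAULT_CUTOFF, ddof: int = 1,
                    ) -> pd.DataFrame:
    """Z ratios of condition A vs condition B with significance flags.

    Per protein: d = mean Z(A) - mean Z(B) (averaging duplicates at the Z
    level); Z ratio = d / SD(all proteins' d).  Proteins unobserved in one
    condition are excluded.  Identical conditions make every d zero and the
    ratio undefined — raised as an error rather than silently divided.
    """
    for cond in (condition_a, condition_b):
        if cond not in set(zmat.conditions):
            raise ValueError(f"condition {cond!r} absent from design")
    za = zmat.z.loc[zmat.conditions == condition_a].mean(axis=0, skipna=True)
    zb = zmat.z.loc[zmat.conditions == condition_b].mean(axis=0, skipna=True)
    d = za - zb
    excluded = d.index[d.isna()].tolist()
    d = d.dropna()
    sd = d.std(ddof=ddof)
    if sd == 0 or np.isnan(sd):
        raise ValueError(
            "SD of Z-score differences is zero: the two conditions are "
            "identical, Z ratios are undefined")
    zratio = d / sd
    assert abs(zratio.std(ddof=ddof) - 1.0) < 1e-9, \
        "Z-ratio vector must have unit SD by construction"
    table = pd.DataFrame({
        f"mean_z_{condition_a}": za.loc[d.index],
        f"mean_z_{condition_b}": zb.loc[d.index],
        "z_ratio": zratio,
        "significant": zratio.abs() >= cutoff,
        "direction": np.where(zratio > 0, "up",
                              np.where(zratio < 0, "down", "none")),
    })
    table.index.name = "protein"
    table.attrs["cutoff"] = cutoff
    table.attrs["excluded"] = excluded
    return table


def derive_probe(enriched_sets: list[tuple[str, set[str] | list[str]]],
                 ) -> set[str]:
    """Intersection of enriched pathways' member proteins.

    The shared members of all significantly down-regulated pathways form the
    probe used to interrogate the interactome.  An empty intersection is a
    valid (empty) probe.
    """
    if not enriched_sets:
        raise ValueError("need at least one enriched set")
    probe = set(enriched_sets[0][1])
    for _, members in enriched_sets[1:]:
        probe &= set(members)
    return probe
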