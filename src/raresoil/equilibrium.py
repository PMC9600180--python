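"""Equilibrium analysis: does the rare:abundant mass ratio track how far
the community has moved from its initial state?

For each post-disturbance sample the ratio of summed rare-taxon to summed
abundant-taxon relative abundance (invading OTUs counted as rare) is
regressed, by ordinary least squares, on the sample's overall-community
Bray-Curtis dissimilarity from the initial samples.  A positive slope
indicates that new community equilibria assemble around the rare taxa.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RelAbundanceTable, TableError
from .classify import CategoryAssignment


def ratio_rare_abundant(
    rel: RelAbundanceTable, assignment: CategoryAssignment
) -> pd.Series:
    """Per-sample ratio of rare-group to abundant-group total abundance.

    Samples whose abundant share is zero are dropped with a warning (the
    ratio is undefined there).  The common-taxa share enters neither
    numerator nor denominator.
    """
    group = assignment.group_of(rel.proportions.index)
    shares = rel.proportions.groupby(group.to_numpy()).sum()
    abundant = shares.loc["abundant"] if "abundant" in shares.index else None
    rare = shares.loc["rare"] if "rare" in shares.index else None
    if abundant is None or rare is None:
        raise TableError("assignment yields no abundant or no rare OTUs")
    zero = abundant == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} samples with zero abundant share",
            stacklevel=2,
        )
    ratio = (rare / abundant)[~zero]
    ratio.name = "rare_abundant_ratio"
    return ratio


def ratio_dissimilarity_regression(
    ratios: pd.Series,
    dissimilarities: pd.Series,
    grouping: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-group OLS of community dissimilarity on the rare:abundant ratio.

    Returns a tidy table (group, slope, intercept, r2, pvalue, n) with the
    two-sided t-test p-value for the slope.  Groups with fewer than three
    paired samples are rejected, as is a group with zero ratio variance
    (undefined slope).
    """
    common = ratios.index.intersection(dissimilarities.index)
    x_all = ratios.loc[common]
    y_all = dissimilarities.loc[common]
    if grouping is None:
        grouping = pd.Series("all", index=common)
    else:
        grouping = pd.Series(grouping).loc[common]
    rows = []
    for g, idx in grouping.groupby(grouping).groups.items():
        x = x_all.loc[idx].to_numpy(dtype=float)
        y = y_all.loc[idx].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3:
            raise TableError(f"group {g!r} has fewer than 3 paired samples")
        if np.ptp(x) == 0:
            raise TableError(f"group {g!r} has zero variance in the ratio")
        fit = stats.linregress(x, y)
        rows.append(
            (g, fit.slope, fit.intercept, fit.rvalue ** 2, fit.pvalue, x.size)
        )
    return pd.DataFrame(
        rows, columns=["group", "slope", "intercept", "r2", "pvalue", "n"]
    )
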