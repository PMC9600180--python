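"""Rarefaction, Shannon diversity of taxon-group subcommunities, and
log response ratios (LRRs) against the initial samples.

Shannon diversity H = -sum(p_i * ln(p_i)) is computed in natural-log units
on the OTUs of one taxon group (abundant, common, rare, or the whole
community), renormalized within the group - equivalent to computing H on
the subset counts directly.  The LRR of a post-disturbance sample against
an initial sample is ln(H_sample / H_initial); by default every
post-disturbance sample is crossed with each same-soil initial replicate
("all pairs"), with a replicate-mean variant available.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OtuTable, TableError
from .classify import CategoryAssignment, GROUPS


def rarefy(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Each column is drawn from the sample's reads by multivariate
    hypergeometric sampling, so column sums equal ``depth`` exactly and the
    expected count of an OTU is ``depth`` times its observed proportion.
    Deterministic given ``seed``.
    """
    totals = table.sample_depths()
    shallow = list(totals.index[totals < depth])
    if shallow:
        raise TableError(
            f"samples shallower than rarefaction depth {depth}: {shallow}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for j, sid in enumerate(table.counts.columns):
        col = table.counts[sid].to_numpy()
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return OtuTable(counts, table.metadata.copy(), true_proportions=table.true_proportions)


def shannon_index(values) -> float:
    """H = -sum(p ln p) over the nonzero entries of a count/proportion vector."""
    v = np.asarray(values, dtype=float)
    v = v[v > 0]
    if v.size == 0:
        return float("nan")
    p = v / v.sum()
    return float(-(p * np.log(p)).sum())


def shannon(
    table: OtuTable,
    assignment: CategoryAssignment | None = None,
    groups=("abundant", "common", "rare"),
) -> pd.DataFrame:
    """Per-sample Shannon diversity of taxon-group subcommunities.

    Returns a tidy table (sample_id, group, shannon).  A group with no
    reads in a sample has undefined diversity and is reported as NaN, not
    zero.  With no assignment only the whole-community value (group
    ``"all"``) is computed.
    """
    rows = []
    counts = table.counts
    if assignment is None:
        group_series = None
        groups = ("all",)
    else:
        group_series = assignment.group_of(counts.index)
        bad = [g for g in groups if g not in GROUPS]
        if bad:
            raise TableError(f"unknown taxon groups: {bad}")
    for g in groups:
        sub = counts if g == "all" else counts.loc[(group_series == g).to_numpy()]
        for sid in counts.columns:
            rows.append((sid, g, shannon_index(sub[sid].to_numpy())))
    out = pd.DataFrame(rows, columns=["sample_id", "group", "shannon"])
    return out


def log_response_ratio(
    div: pd.DataFrame, metadata: pd.DataFrame, pairing: str = "all_pairs"
) -> pd.DataFrame:
    """Pairwise LRRs of Shannon diversity against same-soil initial samples.

    Parameters
    ----------
    div : DataFrame
        Output of :func:`shannon` (sample_id, group, shannon).
    metadata : DataFrame
        Sample metadata (index = sample id).
    pairing : {"all_pairs", "replicate_mean"}
        ``all_pairs`` crosses every post-disturbance sample with each
        same-soil initial replicate; ``replicate_mean`` divides by the mean
        initial diversity instead, giving one LRR per sample and group.

    Pairs in which either member has zero or undefined diversity are
    skipped with a warning (the log ratio is undefined there).
    """
    if pairing not in ("all_pairs", "replicate_mean"):
        raise TableError(f"unknown pairing scheme {pairing!r}")
    d = div.merge(
        metadata[["soil", "treatment", "timepoint", "replicate"]],
        left_on="sample_id",
        right_index=True,
    )
    initial = d[d["timepoint"] == "initial"]
    treated = d[d["timepoint"] != "initial"]
    rows = []
    n_skipped = 0
    for (soil, g), block in treated.groupby(["soil", "group"], sort=False):
        ref = initial[(initial["soil"] == soil) & (initial["group"] == g)]
        href = ref["shannon"].to_numpy()
        if pairing == "replicate_mean":
            ok = np.isfinite(href) & (href > 0)
            hbar = href[ok].mean() if ok.any() else np.nan
            for _, r in block.iterrows():
                if not np.isfinite(r["shannon"]) or r["shannon"] <= 0 or not np.isfinite(hbar):
                    n_skipped += 1
                    continue
                rows.append(
                    (r["sample_id"], "<mean>", soil, r["treatment"], r["timepoint"], g,
                     float(np.log(r["shannon"] / hbar)))
                )
        else:
            for _, r in block.iterrows():
                for _, i in ref.iterrows():
                    if (
                        not np.isfinite(r["shannon"]) or r["shannon"] <= 0
                        or not np.isfinite(i["shannon"]) or i["shannon"] <= 0
                    ):
                        n_skipped += 1
                        continue
                    rows.append(
                        (r["sample_id"], i["sample_id"], soil, r["treatment"],
                         r["timepoint"], g, float(np.log(r["shannon"] / i["shannon"])))
                    )
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} LRR pairs with zero or undefined diversity",
            stacklevel=2,
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "initial_sample_id", "soil", "treatment", "timepoint",
                 "group", "lrr"],
    )


def significance_stars(p: float) -> str:
    """Conventional significance stars at 0.05 / 0.01 / 0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def lrr_contrasts(lrr: pd.DataFrame, between: str = "group") -> pd.DataFrame:
    """Welch t-test contrasts of LRRs between taxon groups or soils.

    ``between="group"`` compares abundant vs rare LRRs within each
    (soil, treatment); ``between="soil"`` compares NCF vs NOF within each
    (treatment, group).
    """
    rows = []
    if between == "group":
        for (soil, tr), block in lrr.groupby(["soil", "treatment"], sort=False):
            a = block.loc[block["group"] == "abundant", "lrr"]
            b = block.loc[block["group"] == "rare", "lrr"]
            if len(a) >= 2 and len(b) >= 2:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                rows.append((soil, tr, "abundant_vs_rare", float(a.mean()),
                             float(b.mean()), float(t), float(p), significance_stars(p)))
        cols = ["soil", "treatment", "contrast", "mean_a", "mean_b", "t", "pvalue", "stars"]
    elif between == "soil":
        for (tr, g), block in lrr.groupby(["treatment", "group"], sort=False):
            a = block.loc[block["soil"] == "NCF", "lrr"]
            b = block.loc[block["soil"] == "NOF", "lrr"]
            if len(a) >= 2 and len(b) >= 2:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                rows.append((tr, g, "NCF_vs_NOF", float(a.mean()), float(b.mean()),
                             float(t), float(p), significance_stars(p)))
        cols = ["treatment", "group", "contrast", "mean_a", "mean_b", "t", "pvalue", "stars"]
    else:
        raise TableError(f"unknown contrast dimension {between!r}")
    return pd.DataFrame(rows, columns=cols)
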