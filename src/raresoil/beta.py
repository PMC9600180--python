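"""Community-structure statistics: Bray-Curtis dissimilarity, principal
coordinate analysis, PERMANOVA, SIMPER, and dissimilarity to the initial
state.

All statistics are implemented from their definitions.  Bray-Curtis between
profiles x and y is sum|x_i - y_i| / sum(x_i + y_i).  PCoA is classical
metric scaling of the Gower-centered squared-distance matrix.  PERMANOVA
partitions the squared distances among model terms (sequential sums of
squares via projection matrices) and assesses each pseudo-F by freely
permuting sample labels.  SIMPER decomposes the mean between-group
Bray-Curtis into additive per-OTU contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import RelAbundanceTable, TableError, timepoint_order
from .classify import CategoryAssignment


@dataclass
class DistanceMatrix:
    """A symmetric, zero-diagonal dissimilarity matrix with sample ids."""

    data: np.ndarray
    ids: list

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.ids = list(self.ids)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise TableError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise TableError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise TableError("distance matrix diagonal is not zero")
        if (self.data < -1e-12).any():
            raise TableError("distances must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    def between(self, a, b) -> float:
        return float(self.data[self.ids.index(a), self.ids.index(b)])


def bray_curtis(rel) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between all samples.

    Accepts a :class:`RelAbundanceTable` or a plain OTUs x samples
    DataFrame of non-negative profiles.
    """
    P = rel.proportions if isinstance(rel, RelAbundanceTable) else pd.DataFrame(rel)
    X = P.to_numpy().T  # samples x OTUs
    if (X < 0).any():
        raise TableError("negative entries in abundance profiles")
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i + 1:] - X[i]).sum(axis=1)
        tot = (X[i + 1:] + X[i]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return DistanceMatrix(D, list(P.columns))


@dataclass
class OrdinationResult:
    """Principal coordinates, eigenvalues, and explained variance."""

    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    proportion_explained: np.ndarray  # per retained (positive) axis


class PCoA(BaseEstimator):
    """Classical metric multidimensional scaling of a distance matrix.

    The squared-distance matrix is double-centered (Gower matrix),
    eigendecomposed, and coordinates are eigenvectors scaled by the square
    root of their eigenvalues.  Negative eigenvalues - possible for
    semi-metric dissimilarities such as Bray-Curtis - are retained in
    ``eigenvalues_`` but their axes are excluded from the coordinates; no
    Lingoes/Cailliez correction is applied.  Explained-variance proportions
    are relative to the sum of positive eigenvalues.
    """

    def __init__(self, eps: float = 1e-10):
        self.eps = eps

    def fit(self, d: DistanceMatrix):
        D2 = d.data ** 2
        n = D2.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ D2 @ J
        vals, vecs = np.linalg.eigh((G + G.T) / 2)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        pos = vals > self.eps * max(vals.max(), 1.0)
        coords = vecs[:, pos] * np.sqrt(vals[pos])
        self.eigenvalues_ = vals
        self.proportion_explained_ = vals[pos] / vals[pos].sum()
        self.coordinates_ = pd.DataFrame(
            coords,
            index=d.ids,
            columns=[f"PCo{i + 1}" for i in range(pos.sum())],
        )
        return self

    def fit_transform(self, d: DistanceMatrix) -> pd.DataFrame:
        return self.fit(d).coordinates_


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Principal-coordinate analysis (functional wrapper over :class:`PCoA`)."""
    est = PCoA().fit(d)
    return OrdinationResult(
        est.coordinates_, est.eigenvalues_, est.proportion_explained_
    )


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def permanova(
    d: DistanceMatrix,
    factors,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a distance matrix.

    Parameters
    ----------
    d : DistanceMatrix
    factors : Series or DataFrame
        One column per model term, aligned to the matrix samples.  Terms
        enter sequentially (Type-I sums of squares) in column order.
    n_perm : int
        Number of free label permutations; the p-value includes the
        observed statistic: p = (1 + #{F* >= F}) / (1 + n_perm).
    seed : int
        Permutation seed.

    Returns a tidy table with one row per term plus Residual and Total
    rows; term and residual R2 sum to one.
    """
    if n_perm < 1:
        raise TableError("n_perm must be >= 1")
    F = pd.DataFrame(factors)
    F = F.loc[d.ids] if F.index.isin(d.ids).all() else F.reset_index(drop=True)
    for col in F.columns:
        counts = F[col].value_counts()
        if (counts < 2).any():
            raise TableError(
                f"factor {col!r} has levels with fewer than 2 samples"
            )
    n = len(d.ids)
    G = -0.5 * (np.eye(n) - 1 / n) @ (d.data ** 2) @ (np.eye(n) - 1 / n)
    ss_total = float(np.trace(G))

    # sequential hat matrices: intercept, then cumulatively added terms
    hats = [np.full((n, n), 1.0 / n)]
    dfs = []
    X = np.ones((n, 1))
    for col in F.columns:
        dummies = pd.get_dummies(F[col], drop_first=True).to_numpy(dtype=float)
        X = np.hstack([X, dummies])
        H = _hat(X)
        dfs.append(np.linalg.matrix_rank(X) - np.linalg.matrix_rank(hats[-1]))
        hats.append(H)
    H_full = hats[-1]
    df_resid = n - np.linalg.matrix_rank(X)
    R = np.eye(n) - H_full
    deltas = [hats[k + 1] - hats[k] for k in range(len(F.columns))]

    def all_f(Gmat):
        # residual SS is non-negative by construction; clip roundoff so a
        # perfectly separated design yields F = +inf rather than noise
        ss_res = max(float(np.sum(R * Gmat)), 0.0)
        ss_terms = [float(np.sum(dH * Gmat)) for dH in deltas]
        with np.errstate(divide="ignore"):
            ms_res = ss_res / df_resid
            f = np.array(
                [
                    (ss / df) / ms_res if ms_res > 0 else np.inf
                    for ss, df in zip(ss_terms, dfs)
                ]
            )
        return f, ss_terms, ss_res

    f_obs, ss_terms, ss_res = all_f(G)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(dfs))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        f_perm, _, _ = all_f(Gp)
        exceed += f_perm >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for name, df_t, ss, f, p in zip(F.columns, dfs, ss_terms, f_obs, pvals):
        rows.append((name, df_t, ss, ss / ss_total, f, p))
    rows.append(("Residual", df_resid, ss_res, ss_res / ss_total, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    out = pd.DataFrame(
        rows, columns=["term", "df", "sum_sq", "r2", "pseudo_f", "pvalue"]
    )
    out.attrs["n_permutations"] = n_perm
    out.attrs["seed"] = seed
    return out


@dataclass
class SimperResult:
    """Per-OTU decomposition of the mean between-group Bray-Curtis."""

    contributions: pd.Series  # per-OTU mean contribution (sums to mean BC)
    mean_dissimilarity: float
    group_pair: tuple
    taxon_group_percent: pd.Series | None = None  # % of total per taxon group


def simper(
    rel,
    groups: pd.Series,
    assignment: CategoryAssignment | None = None,
) -> SimperResult:
    """Similarity-percentage analysis for a two-group comparison.

    The contribution of OTU i is the average over all between-group sample
    pairs (x, y) of |x_i - y_i| / sum_k (x_k + y_k); contributions sum to
    the mean between-group Bray-Curtis dissimilarity.  With a category
    assignment, contributions are also aggregated to abundant/common/rare
    percentages of the total.
    """
    P = rel.proportions if isinstance(rel, RelAbundanceTable) else pd.DataFrame(rel)
    groups = pd.Series(groups)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise TableError(f"SIMPER needs exactly two groups, got {levels}")
    sa = [s for s in P.columns if groups.get(s) == levels[0]]
    sb = [s for s in P.columns if groups.get(s) == levels[1]]
    if not sa or not sb:
        raise TableError("each group must contain at least one sample")
    A = P[sa].to_numpy()
    B = P[sb].to_numpy()
    contrib = np.zeros(P.shape[0])
    n_pairs = 0
    for i in range(A.shape[1]):
        x = A[:, i][:, None]
        num = np.abs(x - B)
        den = (x + B).sum(axis=0)
        den = np.where(den > 0, den, 1.0)
        contrib += (num / den).sum(axis=1)
        n_pairs += B.shape[1]
    contrib /= n_pairs
    contributions = pd.Series(contrib, index=P.index, name="contribution")
    mean_bc = float(contributions.sum())

    pct = None
    if assignment is not None:
        g = assignment.group_of(P.index)
        pct = contributions.groupby(g.to_numpy()).sum() / mean_bc * 100.0
        pct = pct.reindex(["abundant", "common", "rare"], fill_value=0.0)
    return SimperResult(contributions, mean_bc, (levels[0], levels[1]), pct)


def dissimilarity_to_initial(rel: RelAbundanceTable, metadata=None) -> pd.Series:
    """Mean Bray-Curtis between each sample and its soil's initial replicates.

    For initial samples themselves the self-pair is excluded, so the value
    reflects dispersion among initial replicates.
    """
    md = rel.metadata if metadata is None else metadata.loc[rel.samples]
    d = bray_curtis(rel)
    out = {}
    for soil in md["soil"].unique():
        init = list(md.index[(md["soil"] == soil) & (md["timepoint"] == "initial")])
        if not init:
            raise TableError(f"no initial samples for soil {soil!r}")
        members = list(md.index[md["soil"] == soil])
        for s in members:
            refs = [i for i in init if i != s]
            if not refs:
                raise TableError(
                    f"sample {s!r} has no initial reference other than itself"
                )
            out[s] = float(np.mean([d.between(s, i) for i in refs]))
    return pd.Series(out, name="dissimilarity_to_initial").loc[
        [s for s in rel.samples if s in out]
    ]


def neighboring_timepoint_tests(
    dissim: pd.Series, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Welch t-tests of dissimilarity-to-initial between consecutive
    timepoints, per (soil, treatment)."""
    from scipy import stats

    md = metadata.loc[dissim.index]
    rows = []
    for (soil, tr), block in md.groupby(["soil", "treatment"], sort=False):
        if tr == "none":
            continue
        tps = sorted(block["timepoint"].unique(), key=timepoint_order)
        for a, b in zip(tps[:-1], tps[1:]):
            va = dissim[block.index[block["timepoint"] == a]]
            vb = dissim[block.index[block["timepoint"] == b]]
            if len(va) >= 2 and len(vb) >= 2:
                t, p = stats.ttest_ind(va, vb, equal_var=False)
                rows.append((soil, tr, a, b, float(va.mean()), float(vb.mean()),
                             float(t), float(p)))
    return pd.DataFrame(
        rows,
        columns=["soil", "treatment", "timepoint_a", "timepoint_b",
                 "mean_a", "mean_b", "t", "pvalue"],
    )
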