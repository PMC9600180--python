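"""Community-structure statistics against independent oracles:
scikit-bio for PCoA/PERMANOVA cross-checks, brute-force enumeration for
SIMPER and exact permutation p-values."""

import itertools

import numpy as np
import pandas as pd
import pytest

from raresoil import (
    DistanceMatrix,
    bray_curtis,
    dissimilarity_to_initial,
    pcoa,
    permanova,
    simper,
)
from raresoil.containers import TableError


def _profiles(mat, ids=None):
    mat = np.asarray(mat, dtype=float)
    return pd.DataFrame(mat, columns=ids or [f"S{j}" for j in range(mat.shape[1])])


class TestBrayCurtis:
    def test_identical_disjoint_and_hand_example(self):
        P = _profiles(np.array([[0.25, 0.75, 0.25, 1, 0], [0.75, 0.25, 0.75, 0, 1]]).T.T)
        P = _profiles(np.column_stack([[0.25, 0.75], [0.75, 0.25], [0.25, 0.75]]))
        d = bray_curtis(P)
        assert d.between("S0", "S2") == 0.0
        assert d.between("S0", "S1") == pytest.approx(0.5)
        disjoint = _profiles(np.column_stack([[1.0, 0.0], [0.0, 1.0]]))
        assert bray_curtis(disjoint).between("S0", "S1") == 1.0

    def test_negative_entries_rejected(self):
        with pytest.raises(TableError, match="negative"):
            bray_curtis(_profiles(np.array([[-0.1, 1.1], [0.5, 0.5]]).T))

    def test_range_and_symmetry_on_random_profiles(self):
        rng = np.random.default_rng(0)
        X = rng.dirichlet(np.ones(30), size=8).T
        d = bray_curtis(_profiles(X))
        assert (d.data >= 0).all() and (d.data <= 1 + 1e-12).all()
        np.testing.assert_allclose(d.data, d.data.T)

    def test_matches_scipy_definition(self):
        from scipy.spatial.distance import braycurtis

        rng = np.random.default_rng(1)
        X = rng.dirichlet(np.ones(20), size=5)
        d = bray_curtis(_profiles(X.T))
        for i, j in itertools.combinations(range(5), 2):
            assert d.data[i, j] == pytest.approx(braycurtis(X[i], X[j]))


class TestPCoA:
    def test_euclidean_triangle_recovered(self):
        # 3-4-5 right triangle: coordinates must reproduce the distances
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        res = pcoa(DistanceMatrix(D, ["a", "b", "c"]))
        C = res.coordinates.to_numpy()
        rec = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, D, atol=1e-9)

    def test_duplicate_sample_identical_coordinates(self):
        rng = np.random.default_rng(2)
        X = rng.dirichlet(np.ones(15), size=4)
        X = np.vstack([X, X[0]])
        d = bray_curtis(_profiles(X.T))
        res = pcoa(d)
        np.testing.assert_allclose(
            res.coordinates.iloc[0], res.coordinates.iloc[4], atol=1e-9
        )

    def test_axis_ordering_and_proportions(self):
        rng = np.random.default_rng(3)
        d = bray_curtis(_profiles(rng.dirichlet(np.ones(25), size=7).T))
        res = pcoa(d)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.all(np.diff(res.proportion_explained) <= 1e-12)
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_against_skbio(self):
        import skbio

        rng = np.random.default_rng(4)
        X = rng.dirichlet(np.ones(40), size=9)
        d = bray_curtis(_profiles(X.T))
        ours = pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.data, d.ids), method="eigh"
        )
        k = ours.coordinates.shape[1]
        for ax in range(min(3, k)):
            a = ours.coordinates.iloc[:, ax].to_numpy()
            b = ref.samples.iloc[:, ax].to_numpy()
            # eigenvectors are sign-arbitrary
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_asymmetric_input_rejected(self):
        with pytest.raises(TableError, match="symmetric"):
            DistanceMatrix(np.array([[0, 1.0], [0.5, 0]]), ["a", "b"])


def _two_group_dm(rng, n_per=4, shift=0.0, n_feat=12):
    A = rng.normal(0, 1, (n_per, n_feat))
    B = rng.normal(shift, 1, (n_per, n_feat))
    X = np.abs(np.vstack([A, B]))
    X = X / X.sum(axis=1, keepdims=True)
    d = bray_curtis(_profiles(X.T))
    labels = pd.Series(
        ["a"] * n_per + ["b"] * n_per, index=d.ids, name="grp"
    )
    return d, labels


def _exact_p(d, labels):
    """Exhaustive enumeration over all equally-sized relabellings."""
    ids = list(labels.index)
    n = len(ids)
    na = (labels == "a").sum()
    obs = permanova(d, labels, n_perm=1, seed=0)
    f_obs = obs.loc[obs["term"] == "grp", "pseudo_f"].iloc[0]
    f_all = []
    for combo in itertools.combinations(range(n), na):
        lab = np.array(["b"] * n, dtype=object)
        lab[list(combo)] = "a"
        res = permanova(d, pd.Series(lab, index=ids, name="grp"), n_perm=1, seed=0)
        f_all.append(res.loc[res["term"] == "grp", "pseudo_f"].iloc[0])
    f_all = np.array(f_all)
    return f_obs, np.mean(f_all >= f_obs - 1e-12)


class TestPermanova:
    def test_r2_partition_and_p_range(self, ncf_rel):
        md = ncf_rel.metadata
        treated = md.index[md["timepoint"] != "initial"]
        d = bray_curtis(ncf_rel.subset_samples(treated))
        res = permanova(d, md.loc[treated, ["treatment", "timepoint"]], n_perm=99, seed=0)
        assert res["r2"].iloc[:-1].sum() == pytest.approx(1.0)  # terms + residual
        p = res["pvalue"].dropna()
        assert ((p > 0) & (p <= 1)).all()

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        d, labels = _two_group_dm(rng, n_per=4, shift=0.6)
        f_obs, p_exact = _exact_p(d, labels)
        n_perm = 1_999
        res = permanova(d, labels, n_perm=n_perm, seed=1)
        p_mc = res.loc[res["term"] == "grp", "pvalue"].iloc[0]
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) < max(4 * se, 0.02)

    def test_extreme_separation_gives_minimum_p(self):
        # identical within groups, disjoint between groups
        X = np.array([[1, 0], [1, 0], [1, 0], [0, 1], [0, 1], [0, 1]], dtype=float)
        d = bray_curtis(_profiles(X.T))
        labels = pd.Series(list("aaabbb"), index=d.ids, name="grp")
        res = permanova(d, labels, n_perm=999, seed=0)
        p = res.loc[res["term"] == "grp", "pvalue"].iloc[0]
        # observed F is maximal; only permutations reproducing the exact
        # partition (probability 0.1 here) can tie it
        assert p <= 0.15

    def test_null_calibration(self):
        """P-values on structureless data are approximately uniform."""
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(200):
            d, labels = _two_group_dm(rng, n_per=3, shift=0.0, n_feat=8)
            res = permanova(d, labels, n_perm=49, seed=int(rng.integers(2 ** 31)))
            pvals.append(res.loc[res["term"] == "grp", "pvalue"].iloc[0])
        pvals = np.array(pvals)
        assert 0.30 < np.mean(pvals < 0.5) < 0.70
        assert np.mean(pvals <= 0.10) < 0.22

    def test_matches_skbio_pseudo_f(self):
        from skbio.stats.distance import permanova as sk_permanova
        import skbio

        rng = np.random.default_rng(7)
        d, labels = _two_group_dm(rng, n_per=5, shift=0.4)
        ours = permanova(d, labels, n_perm=9, seed=0)
        theirs = sk_permanova(
            skbio.DistanceMatrix(d.data, d.ids), labels.to_numpy(), permutations=9
        )
        assert ours.loc[ours["term"] == "grp", "pseudo_f"].iloc[0] == pytest.approx(
            theirs["test statistic"], rel=1e-9
        )

    def test_small_levels_and_bad_nperm_rejected(self):
        X = np.eye(3)
        d = bray_curtis(_profiles(X))
        labels = pd.Series(["a", "a", "b"], index=d.ids, name="grp")
        with pytest.raises(TableError, match="fewer than 2"):
            permanova(d, labels, n_perm=9)
        labels = pd.Series(["a", "a", "a"], index=d.ids, name="grp")
        with pytest.raises(TableError, match="n_perm"):
            permanova(d, labels, n_perm=0)


class TestSimper:
    def test_contributions_sum_to_mean_bc_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            X = rng.dirichlet(np.ones(rng.integers(3, 25)), size=6)
            P = _profiles(X.T)
            groups = pd.Series(list("aaabbb"), index=P.columns)
            res = simper(P, groups)
            d = bray_curtis(P)
            between = [
                d.data[i, j] for i in range(3) for j in range(3, 6)
            ]
            assert abs(res.contributions.sum() - np.mean(between)) < 1e-9
            assert res.mean_dissimilarity == pytest.approx(np.mean(between))

    def test_identical_groups_zero_contributions(self):
        X = np.tile(np.array([[0.2, 0.3, 0.5]]), (4, 1))
        P = _profiles(X.T)
        res = simper(P, pd.Series(list("aabb"), index=P.columns))
        assert (res.contributions == 0).all()

    def test_matches_brute_force_pairwise_enumeration(self):
        rng = np.random.default_rng(9)
        X = rng.dirichlet(np.ones(3), size=4)  # 3 OTUs, 2+2 samples
        P = _profiles(X.T)
        groups = pd.Series(list("aabb"), index=P.columns)
        res = simper(P, groups)
        expected = np.zeros(3)
        pairs = 0
        for i in (0, 1):
            for j in (2, 3):
                expected += np.abs(X[i] - X[j]) / (X[i] + X[j]).sum()
                pairs += 1
        np.testing.assert_allclose(res.contributions, expected / pairs, atol=1e-12)

    def test_group_percentages_sum_to_100(self, ncf_rel, ncf_assignment):
        md = ncf_rel.metadata
        init = list(md.index[md["timepoint"] == "initial"])
        cell = list(md.index[(md["treatment"] == "HE") & (md["timepoint"] == "R0")])
        groups = pd.Series(["i"] * len(init) + ["t"] * len(cell), index=init + cell)
        res = simper(ncf_rel.subset_samples(init + cell), groups, ncf_assignment)
        assert res.taxon_group_percent.sum() == pytest.approx(100.0)

    def test_requires_exactly_two_groups(self):
        P = _profiles(np.eye(3))
        with pytest.raises(TableError, match="two groups"):
            simper(P, pd.Series(list("abc"), index=P.columns))


class TestDissimilarityToInitial:
    def test_identical_to_initials_gives_zero_and_self_excluded(self):
        prof = np.array([0.4, 0.6])
        X = np.tile(prof, (5, 1)).T
        P = _profiles(X)
        md = pd.DataFrame(
            {
                "soil": "NCF",
                "treatment": ["none"] * 4 + ["DR"],
                "timepoint": ["initial"] * 4 + ["R0"],
                "replicate": [1, 2, 3, 4, 1],
            },
            index=P.columns,
        )
        from raresoil.containers import RelAbundanceTable

        rel = RelAbundanceTable(P, md)
        dis = dissimilarity_to_initial(rel)
        assert dis["S4"] == 0.0
        assert (dis >= 0).all()

    def test_ambient_trajectory_flat(self, ncf_rel):
        dis = dissimilarity_to_initial(ncf_rel)
        md = ncf_rel.metadata
        amb = md.index[md["treatment"] == "AMB"]
        means = dis[amb].groupby(md.loc[amb, "timepoint"]).mean()
        assert means.max() - means.min() < 0.05

    def test_missing_initials_rejected(self):
        P = _profiles(np.eye(2))
        md = pd.DataFrame(
            {"soil": "NCF", "treatment": "DR", "timepoint": "R0", "replicate": [1, 2]},
            index=P.columns,
        )
        from raresoil.containers import RelAbundanceTable

        with pytest.raises(TableError, match="initial"):
            dissimilarity_to_initial(RelAbundanceTable(P, md))
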