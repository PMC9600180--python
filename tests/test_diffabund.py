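"""Negative-binomial Wald pipeline: size factors, dispersion recovery,
test calibration, BH oracle, and the responsive-OTU filter."""

import numpy as np
import pandas as pd
import pytest

from raresoil import (
    NegativeBinomialDE,
    bh_adjust,
    estimate_dispersions,
    nb_wald_test,
    responsive_otus,
    size_factors,
)
from raresoil.containers import TableError


def nb_counts(rng, mu, alpha, size):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size)


class TestSizeFactors:
    def test_doubled_column(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 200, size=50)
        C = pd.DataFrame({"a": base, "b": 2 * base})
        sf = size_factors(C)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)
        np.testing.assert_allclose(sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_columns_unit_factors(self):
        C = pd.DataFrame({"a": [5, 9, 3], "b": [5, 9, 3]})
        np.testing.assert_allclose(size_factors(C), 1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        C = pd.DataFrame(rng.integers(1, 500, size=(40, 5)),
                         columns=list("abcde"))
        sf = size_factors(C)
        sf_perm = size_factors(C[["c", "a", "e", "b", "d"]])
        np.testing.assert_allclose(sf_perm[sf.index], sf)

    def test_no_common_row_falls_back_with_warning(self):
        C = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
        with pytest.warns(UserWarning, match="positive"):
            sf = size_factors(C)
        assert (sf > 0).all()


class TestDispersions:
    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(2)
        C = pd.DataFrame(rng.poisson(50, size=(300, 8)))
        state = estimate_dispersions(C, shrinkage=0.0)
        assert np.nanmedian(state.mom_dispersions) < 0.02

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(3)
        C = pd.DataFrame(nb_counts(rng, 100.0, 0.5, size=(50, 8)))
        state = estimate_dispersions(C, shrinkage=0.0)
        assert np.nanmedian(state.mom_dispersions) == pytest.approx(0.5, rel=0.2)

    def test_infinite_shrinkage_collapses_to_trend(self):
        rng = np.random.default_rng(4)
        C = pd.DataFrame(nb_counts(rng, 80.0, 0.3, size=(60, 6)))
        state = estimate_dispersions(C, shrinkage=np.inf)
        a0, a1 = state.trend_coefficients
        m = (C.to_numpy() / state.size_factors.to_numpy()).mean(axis=1)
        np.testing.assert_allclose(state.dispersions, a0 + a1 / m, rtol=1e-9)

    def test_all_zero_otu_excluded(self):
        C = pd.DataFrame([[0, 0, 0, 0], [10, 12, 9, 11], [3, 5, 2, 4]])
        state = estimate_dispersions(C)
        assert np.isnan(state.dispersions.iloc[0])
        assert np.isfinite(state.dispersions.iloc[1:]).all()

    def test_single_replicate_group_rejected(self):
        C = pd.DataFrame(np.ones((5, 3), dtype=int), columns=list("abc"))
        groups = pd.Series(["x", "y", "y"], index=list("abc"))
        with pytest.raises(TableError, match="2 replicates"):
            estimate_dispersions(C, groups=groups)


class TestWald:
    def _null_data(self, rng, n_otus=2_000, alpha=0.2, n_per=4):
        mu = rng.lognormal(np.log(50), 1.0, n_otus)
        Y = nb_counts(rng, np.tile(mu[:, None], (1, 2 * n_per)), alpha,
                      (n_otus, 2 * n_per))
        C = pd.DataFrame(Y, columns=[f"s{j}" for j in range(2 * n_per)])
        y = pd.Series(["a"] * n_per + ["b"] * n_per, index=C.columns)
        return C, y

    def test_type_one_error_calibrated(self):
        """Null NB data: rejection rate at p<0.05 inside the binomial CI."""
        rng = np.random.default_rng(5)
        C, y = self._null_data(rng)
        de = NegativeBinomialDE().fit(C, y)
        p = de.results_["pvalue"].dropna()
        rate = (p < 0.05).mean()
        half = 1.96 * np.sqrt(0.05 * 0.95 / len(p))
        assert abs(rate - 0.05) < half + 0.005

    def test_power_for_fourfold_change(self):
        """Planted 4-fold changes at depth-10k proportions are detected."""
        rng = np.random.default_rng(6)
        n_sig, n_null = 600, 1_400
        mu_null = rng.lognormal(np.log(30), 1.0, n_null)
        # 4-fold changes around proportion 1e-3 at depth 10,000 (counts
        # 10 vs 40), planted in both directions so median-of-ratios
        # normalization stays honest (an all-up design would alias the
        # effect into the size factors)
        up = np.arange(n_sig) % 2 == 0
        mu_ref = np.where(up, 10.0, 40.0)
        mu_alt = np.where(up, 40.0, 10.0)
        Ya = np.hstack([
            nb_counts(rng, np.tile(mu_ref[:, None], (1, 4)), 0.2, (n_sig, 4)),
            nb_counts(rng, np.tile(mu_alt[:, None], (1, 4)), 0.2, (n_sig, 4)),
        ])
        Yn = nb_counts(rng, np.tile(mu_null[:, None], (1, 8)), 0.2, (n_null, 8))
        C = pd.DataFrame(np.vstack([Ya, Yn]), columns=[f"s{j}" for j in range(8)])
        y = pd.Series(["a"] * 4 + ["b"] * 4, index=C.columns)
        de = NegativeBinomialDE().fit(C, y)
        q_planted = de.results_["qvalue"].iloc[:n_sig]
        assert (q_planted < 0.05).mean() > 0.8

    def test_label_swap_negates_lfc(self):
        rng = np.random.default_rng(7)
        C, y = self._null_data(rng, n_otus=50)
        state = estimate_dispersions(C, groups=y)
        a = list(y.index[y == "a"])
        b = list(y.index[y == "b"])
        fwd = nb_wald_test(C, state, (a, b))
        rev = nb_wald_test(C, state, (b, a))
        np.testing.assert_allclose(fwd["lfc"], -rev["lfc"], atol=1e-8)
        np.testing.assert_allclose(fwd["pvalue"], rev["pvalue"], atol=1e-10)

    def test_zero_group_flagged_with_p_one(self):
        C = pd.DataFrame(
            [[0, 0, 0, 5, 6, 7], [10, 12, 9, 11, 10, 12]],
            columns=[f"s{j}" for j in range(6)],
        )
        y = pd.Series(["a"] * 3 + ["b"] * 3, index=C.columns)
        state = estimate_dispersions(C, groups=y)
        res = nb_wald_test(C, state, (list(C.columns[:3]), list(C.columns[3:])))
        assert res["flag"].iloc[0] == "zero_group"
        assert res["pvalue"].iloc[0] == 1.0

    def test_empty_contrast_group_rejected(self):
        C = pd.DataFrame([[1, 2], [3, 4]], columns=["a", "b"])
        state = estimate_dispersions(pd.DataFrame(np.ones((2, 4), dtype=int)))
        with pytest.raises(TableError, match="non-empty"):
            nb_wald_test(C, state, ([], ["a"]))


class TestBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_all_ones(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(TableError):
            bh_adjust([0.5, 1.2])

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.random(rng.integers(1, 1_000))
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(9)
        p = rng.random(500)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestResponsive:
    def _fake_results(self):
        return pd.DataFrame(
            {
                "base_mean": [10, 10, 10, 10],
                "lfc": [2.5, 0.5, -3.0, 2.0],
                "lfc_shrunk": [2.2, 0.5, -2.8, 0.9],
                "se": 0.5,
                "stat": [4, 1, -5, 4],
                "pvalue": [0.001, 0.3, 0.0001, 0.001],
                "qvalue": [0.004, 0.4, 0.0004, 0.04],
                "flag": "",
            },
            index=["o1", "o2", "o3", "o4"],
        )

    def test_filter_thresholds_and_directions(self):
        filtered, summary = responsive_otus(self._fake_results())
        # o2 fails q, o4 fails |shrunken lfc| > 1
        assert list(filtered.index) == ["o1", "o3"]
        assert list(filtered["direction"]) == ["up", "down"]

    def test_borderline_lfc_excluded(self):
        res = self._fake_results()
        res.loc["o1", "lfc_shrunk"] = 0.5  # q=0.004 but small effect
        filtered, _ = responsive_otus(res)
        assert "o1" not in filtered.index

    def test_idempotent(self):
        filtered, _ = responsive_otus(self._fake_results())
        twice, _ = responsive_otus(filtered)
        pd.testing.assert_frame_equal(
            filtered, twice[filtered.columns]
        )

    def test_empty_results_zero_counts(self):
        empty = self._fake_results().iloc[:0]
        filtered, summary = responsive_otus(empty)
        assert filtered.empty and summary.empty

    def test_rare_planted_effects_dominate_counts(self, small_series, ncf_assignment):
        """With rare-OTU blooms in the generator, responsive rare OTUs
        outnumber responsive abundant OTUs."""
        md = small_series.metadata
        init = small_series.initial_samples("NCF")
        cell = list(
            md.index[(md["soil"] == "NCF") & (md["treatment"] == "HE")
                     & (md["timepoint"] == "R0")]
        )
        sub = small_series.subset_samples(init + cell)
        y = pd.Series(["initial"] * len(init) + ["treated"] * len(cell),
                      index=init + cell)
        de = NegativeBinomialDE(ref_level="initial").fit(sub, y)
        filtered, summary = responsive_otus(de.results_, ncf_assignment)
        by_group = summary.groupby("category_group")["n_otus"].sum()
        assert by_group.get("rare", 0) > by_group.get("abundant", 0)
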