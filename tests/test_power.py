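import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import spotpower as spw
from spotpower import BootstrapSpec, DEOptions, ValidationError
from spotpower.power import power_from_adjusted_pvalues


@pytest.fixture(scope="module")
def roi(small_dataset):
    _, ds = small_dataset
    return spw.select_roi(ds, "roi"), ds


class TestBootstrapReplicates:
    def test_sample_sizes_are_n_times_N(self, roi):
        sel, ds = roi
        spec = BootstrapSpec(n_spots=80, N=6, B=1, seed=0)
        a, b = spw.bootstrap_replicates(sel, ds, spec, repetition=0)
        assert len(a) == len(b) == 480

    def test_imbalanced_design(self, roi):
        sel, ds = roi
        spec = BootstrapSpec(n_spots=(10, 20), N=(3, 2), B=1, seed=0)
        a, b = spw.bootstrap_replicates(sel, ds, spec, repetition=0)
        assert (len(a), len(b)) == (30, 40)

    def test_indices_come_from_condition_pools(self, roi):
        sel, ds = roi
        spec = BootstrapSpec(n_spots=15, N=2, B=1, seed=1)
        a, b = spw.bootstrap_replicates(sel, ds, spec, repetition=3)
        pools = list(sel.spots_per_condition.values())
        assert set(a) <= set(pools[0]) and set(b) <= set(pools[1])

    def test_degenerate_pool_of_one(self, small_dataset):
        _, ds = small_dataset
        sel = spw.ROISelection(
            "roi", {"cond1": np.array([0]), "cond2": np.array([1])}
        )
        spec = BootstrapSpec(n_spots=5, N=2, B=1, seed=0)
        a, b = spw.bootstrap_replicates(sel, ds, spec, repetition=0)
        assert set(a) == {0} and set(b) == {1}

    def test_repetition_stream_deterministic(self, roi):
        sel, ds = roi
        spec = BootstrapSpec(n_spots=20, N=3, B=10, seed=7)
        a1, b1 = spw.bootstrap_replicates(sel, ds, spec, repetition=4)
        a2, b2 = spw.bootstrap_replicates(sel, ds, spec, repetition=4)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(b1, b2)
        a3, _ = spw.bootstrap_replicates(sel, ds, spec, repetition=5)
        assert not np.array_equal(a1, a3)


class TestLogNormalize:
    def test_closed_form_values(self):
        counts = np.array([[100.0], [9900.0]])
        x = spw.lognormalize(counts)
        assert x[0, 0] == pytest.approx(np.log(101.0))
        assert spw.lognormalize(np.array([[0.0], [5.0]]))[0, 0] == 0.0

    def test_scale_invariance_per_spot(self):
        rng = np.random.default_rng(0)
        c = rng.poisson(3.0, size=(20, 10)).astype(float) + 1
        np.testing.assert_allclose(spw.lognormalize(c), spw.lognormalize(2 * c))

    def test_zero_library_spot_is_named(self):
        c = np.zeros((3, 2))
        c[:, 0] = 1
        with pytest.raises(ValidationError, match=r"\[1\]"):
            spw.lognormalize(c)


class TestWilcoxonDE:
    def test_identical_groups_yield_zero_logfc_and_no_tests(self):
        rng = np.random.default_rng(1)
        x = np.log1p(rng.poisson(2.0, size=(30, 12)).astype(float))
        res = spw.wilcoxon_de(x, x, n_genes_total=30)
        np.testing.assert_allclose(res["avg_logfc"], 0.0, atol=1e-12)
        assert not res["tested"].any()  # |logfc| < 0.25 everywhere

    def test_complete_separation_matches_exact_permutation_p(self):
        a = np.array([[1.0, 2, 3, 4, 5]])
        b = np.array([[6.0, 7, 8, 9, 10]])
        res = spw.wilcoxon_de(a, b, n_genes_total=1, min_pct=0, logfc_threshold=0)
        # complete separation of 5 vs 5: the only splits at least as extreme
        # are the two one-sided extremes, so p = 2 / C(10, 5)
        assert res["p_value"].iloc[0] == pytest.approx(2 / 252, abs=1e-12)

    def test_undetected_gene_untested(self):
        a = np.zeros((1, 10))
        b = np.zeros((1, 10))
        res = spw.wilcoxon_de(a, b, n_genes_total=1)
        assert res["pct1"].iloc[0] == 0 and res["pct2"].iloc[0] == 0
        assert not res["tested"].iloc[0]
        assert np.isnan(res["p_value"].iloc[0])

    def test_constant_tested_gene_gets_p_one(self):
        a = np.full((1, 6), 2.0)
        b = np.full((1, 6), 2.0)
        res = spw.wilcoxon_de(a, b, n_genes_total=1, min_pct=0, logfc_threshold=0)
        assert res["p_value"].iloc[0] == 1.0

    def test_bonferroni_uses_total_gene_count(self):
        rng = np.random.default_rng(2)
        a = np.log1p(rng.poisson(5.0, (4, 40)).astype(float))
        b = np.log1p(rng.poisson(1.0, (4, 40)).astype(float))
        res = spw.wilcoxon_de(a, b, n_genes_total=1000, min_pct=0, logfc_threshold=0)
        t = res["tested"]
        np.testing.assert_allclose(
            res.loc[t, "p_adj"], np.minimum(1.0, res.loc[t, "p_value"] * 1000)
        )

    @pytest.mark.parametrize("n1,n2", [(3, 5), (8, 8), (2, 7)])
    def test_statistic_equals_rank_sum_oracle(self, n1, n2):
        """The normal/exact machinery and a direct rank-sum agree on U."""
        rng = np.random.default_rng(n1 * 10 + n2)
        a, b = rng.normal(0, 1, n1), rng.normal(1, 1, n2)
        u_scipy = scipy.stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        ranks = scipy.stats.rankdata(np.concatenate([a, b]))
        u_oracle = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        assert u_scipy == u_oracle


class TestPowerFromAdjustedPvalues:
    @given(
        padj=hnp.arrays(
            float,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=25),
            elements=st.one_of(st.floats(0, 1), st.just(np.nan)),
        ),
        alpha=st.floats(0.01, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce_count(self, padj, alpha):
        power = power_from_adjusted_pvalues(padj, alpha)
        G, B = padj.shape
        for g in range(G):
            n_sig = sum(
                1 for v in padj[g] if (not np.isnan(v)) and v < alpha
            )
            assert power[g] == n_sig / B

    def test_power_is_multiple_of_one_over_B(self):
        rng = np.random.default_rng(0)
        padj = rng.uniform(0, 1, size=(10, 20))
        power = power_from_adjusted_pvalues(padj, 0.3)
        np.testing.assert_allclose(power * 20, np.round(power * 20))


class TestEstimatePower:
    def test_power_table_schema_and_bounds(self, roi):
        sel, ds = roi
        spec = BootstrapSpec(n_spots=30, N=2, B=8, alpha=0.05, seed=3)
        tab = spw.estimate_power(sel, ds, spec)
        assert list(tab.columns) == [
            "gene", "pi_g", "abs_beta_g", "N", "power", "B", "alpha",
        ]
        assert ((tab["power"] >= 0) & (tab["power"] <= 1)).all()
        assert ((tab["pi_g"] >= 0) & (tab["pi_g"] <= 1)).all()
        assert (tab["abs_beta_g"] >= 0).all()
        np.testing.assert_allclose(tab["power"] * 8, np.round(tab["power"] * 8))

    def test_monotone_in_alpha(self, roi):
        sel, ds = roi
        tabs = {}
        for alpha in (0.05, 0.5):
            spec = BootstrapSpec(n_spots=30, N=2, B=10, alpha=alpha, seed=3)
            tabs[alpha] = spw.estimate_power(sel, ds, spec).set_index("gene")
        joined = tabs[0.05].join(tabs[0.5], rsuffix="_hi", how="inner")
        assert (joined["power_hi"] >= joined["power"]).all()

    def test_deterministic_given_seed(self, roi):
        sel, ds = roi
        spec = BootstrapSpec(n_spots=25, N=2, B=5, seed=11)
        t1 = spw.estimate_power(sel, ds, spec)
        t2 = spw.estimate_power(sel, ds, spec)
        assert t1.equals(t2)


class TestPowerVsNullCheck:
    def test_stratified_summary(self, roi, small_dataset):
        design, ds = small_dataset
        sel, _ = roi
        spec = BootstrapSpec(n_spots=40, N=3, B=10, seed=5)
        tab = spw.estimate_power(sel, ds, spec)
        qc = spw.power_vs_null_check(tab, spw.truth_table(design))
        assert set(qc["stratum"]) == {0.0, 1.0}
        null_row = qc.loc[qc["stratum"] == 0.0].iloc[0]
        deg_row = qc.loc[qc["stratum"] == 1.0].iloc[0]
        assert null_row["n_genes"] == 48 and deg_row["n_genes"] == 12
        assert deg_row["mean_power"] > null_row["mean_power"]

    def test_empty_truth_rejected(self, roi):
        import pandas as pd

        sel, ds = roi
        with pytest.raises(ValidationError):
            spw.power_vs_null_check(pd.DataFrame(), pd.DataFrame())

    def test_single_stratum_summary(self):
        import pandas as pd

        records = pd.DataFrame({"gene": ["a", "b"], "power": [0.5, 0.7]})
        truth = pd.DataFrame({"gene": ["a", "b"], "true_logfc": [1.0, 1.0]})
        qc = spw.power_vs_null_check(records, truth)
        assert len(qc) == 1
        assert qc["mean_power"].iloc[0] == pytest.approx(0.6)
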