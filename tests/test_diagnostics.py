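"""FDR, genomic control, stratification and QQ data."""

import numpy as np
import pytest
from scipy import stats

import binlmm as bl
from binlmm.diagnostics import CHI2_1_MEDIAN, STRATA


def _matrix(calls):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return bl.GenotypeMatrix([f"s{i}" for i in range(n)], [f"m{j}" for j in range(m)],
                             ["1"] * m, np.arange(m) + 1, calls)


class TestBhFdr:
    @pytest.mark.parametrize("p,q,expected", [
        ([0.001, 0.2, 0.9], 0.05, [True, False, False]),
        ([1.0, 1.0, 1.0], 0.05, [False, False, False]),
        ([0.01, 0.012, 0.013], 0.05, [True, True, True]),
    ])
    def test_hand_step_up(self, p, q, expected):
        assert list(bl.bh_fdr(p, q)) == expected

    def test_empty_input(self):
        assert bl.bh_fdr([], 0.05).size == 0

    def test_nan_excluded_from_test_count(self):
        # with the NaN ignored, m=3 and all three pass at q=0.05
        calls = bl.bh_fdr([0.01, np.nan, 0.012, 0.013], 0.05)
        assert list(calls) == [True, False, True, True]

    def test_q10_superset_of_q05(self, rng):
        p = rng.uniform(size=500) ** 3
        assert (bl.bh_fdr(p, 0.05) <= bl.bh_fdr(p, 0.10)).all()


class TestGenomicControl:
    def test_definition_and_linearity(self):
        assert bl.genomic_control([CHI2_1_MEDIAN] * 5) == pytest.approx(1.0)
        s = np.array([0.1, 0.5, 1.0, 2.0, 5.0])
        assert bl.genomic_control(2 * s) == pytest.approx(2 * bl.genomic_control(s))

    def test_chi2_null_calibrated(self, rng):
        draws = rng.chisquare(1, size=100_000)
        assert 0.98 <= bl.genomic_control(draws) <= 1.02

    def test_permutation_invariant(self, rng):
        s = rng.chisquare(1, size=101)
        assert bl.genomic_control(s) == bl.genomic_control(rng.permutation(s))

    def test_pvalue_route_matches_statistic_route(self, rng):
        s = rng.chisquare(1, size=999)
        p = stats.chi2.sf(s, 1)
        assert bl.genomic_control(p=p) == pytest.approx(bl.genomic_control(s), rel=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bl.genomic_control([])


class TestMonomorphicFilter:
    @pytest.mark.parametrize("column,kept", [
        ([0, 0, 0, 2], False),   # constant in A
        ([0, 2, 0, 2], True),
        ([0, 2, 2, 2], False),   # constant in B
    ])
    def test_toy_rules(self, column, kept):
        G = _matrix(np.array(column)[:, None])
        labels = np.array(["A", "A", "B", "B"])
        Gf, removed = bl.filter_monomorphic_within(G, labels)
        assert (Gf.n_markers == 1) is kept
        assert (len(removed) == 0) is kept

    def test_counts_partition(self, small_panel, rng):
        _, G, labels, _, _ = small_panel
        Gf, removed = bl.filter_monomorphic_within(G, labels)
        assert Gf.n_markers + len(removed) == G.n_markers

    def test_wrong_label_count_raises(self):
        G = _matrix(np.array([[0], [1], [2]]))
        with pytest.raises(ValueError):
            bl.filter_monomorphic_within(G, np.array(["A", "B", "C"]))


class TestVarianceRatioStrata:
    def test_hand_ratios(self):
        # focal MAFs 0.5, 0.3, 0.1 vs other MAF 0.1, 0.3, 0.5
        # ratios: 0.5/0.18=2.78 -> common; 1 -> similar; 0.18/0.5=0.36 -> rare
        calls = np.zeros((20, 3), dtype=np.int8)
        calls[:5, 0] = 2          # focal freq 0.5
        calls[10:11, 0] = 2       # other freq 0.1
        calls[:3, 1] = 2          # focal freq 0.3
        calls[10:13, 1] = 2       # other freq 0.3
        calls[:1, 2] = 2          # focal freq 0.1
        calls[10:15, 2] = 2       # other freq 0.5
        G = _matrix(calls)
        labels = np.array(["F"] * 10 + ["O"] * 10)
        strata = bl.variance_ratio_strata(G, labels, focal="F")
        assert list(strata.stratum) == ["common_in_focal", "similar", "rare_in_focal"]
        assert strata.ratio[0] == pytest.approx((2 * .5 * .5) / (2 * .1 * .9))

    def test_boundaries_closed_middle_bin(self):
        strata_of = lambda r: ("rare_in_focal" if r < 0.8
                               else "common_in_focal" if r > 1.25 else "similar")
        # mirror the binning rule on exact boundary ratios
        assert strata_of(0.80) == "similar" and strata_of(1.25) == "similar"

    def test_invariant_to_allele_flip(self, small_panel):
        _, G, labels, _, _ = small_panel
        s1 = bl.variance_ratio_strata(G, labels, focal="tropical")
        G2 = G.copy()
        G2.calls = (2 - G2.calls).astype(np.int8)
        s2 = bl.variance_ratio_strata(G2, labels, focal="tropical")
        assert list(s1.stratum) == list(s2.stratum)
        np.testing.assert_allclose(s1.ratio, s2.ratio, rtol=1e-12)

    def test_strata_partition_markers(self, small_panel):
        _, G, labels, _, _ = small_panel
        strata = bl.variance_ratio_strata(G, labels, focal="tropical")
        counts = {s: (strata.stratum == s).sum() for s in STRATA}
        assert sum(counts.values()) == G.n_markers


class TestBernoulliVariance:
    @pytest.mark.parametrize("p,v", [
        (0.18, 0.1476), (0.48, 0.2496), (0.05, 0.0475), (0.5, 0.25), (0.0, 0.0),
    ])
    def test_values(self, p, v):
        assert bl.bernoulli_variance(p) == pytest.approx(v, abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            bl.bernoulli_variance(bad)


class TestQqPoints:
    def test_single_value(self):
        exp, obs = bl.qq_points([0.5])
        assert exp[0] == pytest.approx(-np.log10(0.5))
        assert obs[0] == pytest.approx(-np.log10(0.5))

    def test_uniform_grid_on_diagonal(self):
        m = 200
        p = np.arange(1, m + 1) / (m + 1)
        exp, obs = bl.qq_points(p)
        assert np.abs(exp - obs).max() < 1e-12

    def test_empty(self):
        exp, obs = bl.qq_points([])
        assert exp.size == 0 and obs.size == 0


class TestStratifiedDiagnostics:
    def test_partition_and_identical_tables(self, small_panel):
        cfg, G, labels, X, K = small_panel
        y = bl.simulate_binary_trait(labels, cfg.prevalence_map, 55)
        lmm_tab = bl.run_lmm_gwas(y, G, X, K)
        mlm_tab = bl.run_mlm_gwas(y, G, X, K)
        strata = bl.variance_ratio_strata(G, labels, focal="tropical")
        report = bl.stratified_diagnostics(lmm_tab, mlm_tab, strata)
        t = report.table
        for model in ("LMM", "MLM"):
            sub = t[(t["model"] == model) & (t["stratum"] != "all")]
            total = int(t.loc[(t["model"] == model) & (t["stratum"] == "all"),
                              "n_markers"].iloc[0])
            assert sub["n_markers"].sum() == total
        # identical input tables give identical per-stratum lambdas
        lmm2 = lmm_tab.copy()
        lmm2["model"] = "MLM"   # reuse the same stats under the other tag
        report2 = bl.stratified_diagnostics(lmm_tab, lmm2, strata)
        t2 = report2.table.pivot(index="stratum", columns="model", values="lambda")
        np.testing.assert_allclose(t2["LMM"], t2["MLM"], rtol=1e-6)

    def test_marker_mismatch_raises(self, small_panel):
        cfg, G, labels, X, K = small_panel
        y = bl.simulate_binary_trait(labels, cfg.prevalence_map, 55)
        lmm_tab = bl.run_lmm_gwas(y, G, X, K)
        strata = bl.variance_ratio_strata(G, labels, focal="tropical")
        with pytest.raises(ValueError):
            bl.stratified_diagnostics(lmm_tab, lmm_tab.iloc[::-1].reset_index(drop=True),
                                      strata)
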