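"""Ground-truth generator: invariants, determinism, distributional sanity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tucseq.simdata import (
    LN2,
    SimulationConfig,
    apply_dropout,
    simulate_bisulfite,
    simulate_conversion_reads,
    simulate_gene_reads,
    simulate_truth,
)


def pooled_frequency(hist):
    return (hist["k"] * hist["count"]).sum() / (hist["n"] * hist["count"]).sum()


class TestSimulateTruth:
    def test_steady_state_identity(self, small_truth):
        t = small_truth.turnover
        assert np.allclose(t["E_true"], t["S_true"] * t["HL_true"] / LN2, atol=1e-9)
        assert (t["HL_true"] > 0).all()

    def test_deterministic_given_seed(self, small_config):
        a = simulate_truth(small_config)
        b = simulate_truth(small_config)
        pd.testing.assert_frame_equal(a.turnover, b.turnover)
        pd.testing.assert_frame_equal(a.methylation, b.methylation)

    def test_degenerate_config_all_conditions_identical(self):
        cfg = SimulationConfig(n_genes=50, buffering_fraction=0.0, deg_fraction=0.0, seed=1)
        t = simulate_truth(cfg).turnover.pivot(index="gene", columns="condition")
        hl = t["HL_true"]
        assert (hl.nunique(axis=1) == 1).all()

    def test_fraction_sum_validated(self):
        with pytest.raises(ValueError, match="exceed"):
            SimulationConfig(buffering_fraction=0.7, deg_fraction=0.6)

    def test_buffered_genes_anticorrelated_and_stable(self):
        cfg = SimulationConfig(n_genes=600, buffering_fraction=1.0, deg_fraction=0.0, seed=2)
        tr = simulate_truth(cfg)
        t = tr.turnover.pivot(index="gene", columns="condition")
        lfc_hl = np.log2(t[("HL_true")]["WT.d4"] / t[("HL_true")]["WT.d0"])
        lfc_s = np.log2(t[("S_true")]["WT.d4"] / t[("S_true")]["WT.d0"])
        lfc_e = np.log2(t[("E_true")]["WT.d4"] / t[("E_true")]["WT.d0"])
        r = stats.spearmanr(lfc_hl, lfc_s).statistic
        assert -0.95 < r < -0.6
        assert (lfc_e.abs() < 1.0).all()

    def test_deg_genes_change_steady_state(self, small_truth):
        gc = small_truth.gene_class.set_index("gene")["gene_class"]
        t = small_truth.turnover.pivot(index="gene", columns="condition")
        lfc_e = np.log2(t[("E_true")]["WT.d4"] / t[("E_true")]["WT.d0"])
        deg = gc.isin(["deg_S", "deg_HL"])
        assert (lfc_e[deg].abs() > 1.0).all()
        assert np.allclose(lfc_e[gc == "constant"], 0.0)


class TestConversionReads:
    def test_unlabeled_frequency_near_p_err(self, small_truth, small_config):
        hist, _ = simulate_conversion_reads(small_truth, small_config, "WT.d0", 1, labeled=False)
        freq = pooled_frequency(hist)
        n_total = (hist["n"] * hist["count"]).sum()
        se = np.sqrt(small_config.p_err * (1 - small_config.p_err) / n_total)
        assert abs(freq - small_config.p_err) < 3 * se

    def test_labeled_frequency_elevated(self, small_truth, small_config):
        lab, _ = simulate_conversion_reads(small_truth, small_config, "WT.d0", 1, labeled=True)
        ctrl, _ = simulate_conversion_reads(small_truth, small_config, "WT.d0", 1, labeled=False)
        assert pooled_frequency(lab) > pooled_frequency(ctrl)

    def test_one_halflife_elapsed_gives_half_new_reads(self):
        rng = np.random.default_rng(0)
        hist = simulate_gene_reads(0.5, 20_000, rng)
        # new reads convert at p_new=0.04 over ~30 U; classify by k>=2
        frac_converted = hist.loc[hist["k"] >= 2, "count"].sum() / hist["count"].sum()
        p_new_read = 1 - stats.binom.cdf(1, 30, 0.04)  # P(k>=2 | new), approx
        assert abs(frac_converted - 0.5 * p_new_read) < 0.02

    def test_determinism(self, small_truth, small_config):
        a = simulate_conversion_reads(small_truth, small_config, "WT.d4", 2, True)
        b = simulate_conversion_reads(small_truth, small_config, "WT.d4", 2, True)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_series_equal(a[1], b[1])

    def test_unknown_condition_raises(self, small_truth, small_config):
        with pytest.raises(KeyError):
            simulate_conversion_reads(small_truth, small_config, "WT.d99", 1, True)


class TestApplyDropout:
    def test_zero_strength_is_identity(self, small_truth, small_config):
        hist, counts = simulate_conversion_reads(small_truth, small_config, "WT.d0", 1, True)
        out_h, out_c = apply_dropout(hist, counts, small_truth, "WT.d0", 0.0, rng=1)
        pd.testing.assert_frame_equal(out_h, hist)
        pd.testing.assert_series_equal(out_c, counts)

    def test_counts_non_increasing(self, small_truth, small_config):
        hist, counts = simulate_conversion_reads(small_truth, small_config, "WT.d0", 1, True)
        _, out_c = apply_dropout(hist, counts, small_truth, "WT.d0", 0.5, rng=1)
        assert (out_c <= counts).all()

    def test_full_ntr_gene_retention_half(self):
        # construct a truth with HL so small that pi ~ 1
        cfg = SimulationConfig(n_genes=30, hl_range=(0.01, 0.0101), seed=3,
                               buffering_fraction=0, deg_fraction=0)
        tr = simulate_truth(cfg)
        hist, counts = simulate_conversion_reads(tr, cfg, "WT.d0", 1, True,
                                                 apply_configured_dropout=False)
        _, out_c = apply_dropout(hist, counts, tr, "WT.d0", 0.5, rng=5)
        retention = out_c.sum() / counts.sum()
        assert abs(retention - 0.5) < 0.02

    def test_retention_decreases_with_ntr(self, small_config):
        cfg = small_config.replace(seed=11, n_genes=300)
        tr = simulate_truth(cfg)
        hist, counts = simulate_conversion_reads(tr, cfg, "WT.d0", 1, True)
        _, out_c = apply_dropout(hist, counts, tr, "WT.d0", 0.5, rng=7)
        pi = tr.pi_true("WT.d0")
        ok = counts > 50
        log_ret = np.log((out_c[ok] + 1) / counts[ok])
        slope = stats.linregress(pi[ok], log_ret).slope
        assert slope < -0.1

    def test_invalid_strength(self, small_truth, small_config):
        hist, counts = simulate_conversion_reads(small_truth, small_config, "WT.d0", 1, True)
        with pytest.raises(ValueError):
            apply_dropout(hist, counts, small_truth, "WT.d0", 1.5)


class TestBisulfite:
    def test_perfect_conversion_unmethylated_all_converted(self, small_truth):
        cfg = small_truth.config.replace(bs_conversion_rate=1.0)
        sites = simulate_bisulfite(small_truth, "WT", 1, cfg)
        meth = small_truth.methylation
        unmeth = ~meth["is_methylated"].to_numpy()
        assert (sites.loc[unmeth, "non_converted"] == 0).all()

    def test_fully_methylated_site_never_converts(self):
        cfg = SimulationConfig(n_genes=60, n_methylated_sites=20,
                               methylation_rate_range=(1.0, 1.0), seed=4)
        tr = simulate_truth(cfg)
        sites = simulate_bisulfite(tr, "WT", 1)
        meth_rows = tr.methylation["is_methylated"].to_numpy()
        assert (sites.loc[meth_rows, "non_converted"] == sites.loc[meth_rows, "coverage"]).all()

    def test_expected_nonconversion_rate(self):
        # rate 0.15, conversion 0.99 -> E[non-conv]/coverage = 0.15 + 0.85*0.01 = 0.1585
        cfg = SimulationConfig(n_genes=400, n_methylated_sites=200,
                               methylation_rate_range=(0.15, 0.15),
                               bs_conversion_rate=0.99, bs_coverage_mean=100, seed=5)
        tr = simulate_truth(cfg)
        sites = simulate_bisulfite(tr, "WT", 1)
        meth_rows = tr.methylation["is_methylated"].to_numpy()
        mean_nonconv = (
            sites.loc[meth_rows, "non_converted"].sum() / sites.loc[meth_rows, "coverage"].sum()
        )
        assert abs(mean_nonconv * 100 - 15.85) < 0.8

    def test_knockout_loses_dependent_sites_only(self, small_truth):
        meth = small_truth.methylation
        dep = meth["nsun2_dependent"]
        assert (meth.loc[dep, "rate_KO"] == 0).all()
        ind = meth["is_methylated"] & ~dep
        assert (meth.loc[ind, "rate_KO"] == meth.loc[ind, "rate_WT"]).all()
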