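"""m5C site calling: filters, Fisher oracle, consensus and dependence logic."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from tucseq.m5c import (
    ConversionContext,
    SiteFilters,
    call_sites,
    consensus_sites,
    dependent_sites,
    overlap_with_dynamics,
    sites_to_bed,
    _fisher_one_sided,
)


def site_frame(rows):
    """rows: (chrom, pos, strand, gene, coverage, non_converted)"""
    return pd.DataFrame(
        rows, columns=["chrom", "pos_1based", "strand", "gene", "coverage", "non_converted"]
    )


def hypergeom_tail_brute(a, b, c, d):
    """P(X >= a) for the 2x2 table by explicit hypergeometric summation."""
    n_pop, n_succ, n_draw = a + b + c + d, a + c, a + b
    denom = comb(n_pop, n_draw)
    total = 0
    for x in range(a, min(n_succ, n_draw) + 1):
        total += comb(n_succ, x) * comb(n_pop - n_succ, n_draw - x)
    return total / denom


class TestFisher:
    @pytest.mark.parametrize(
        "table",
        [(5, 45, 10, 990), (25, 25, 10, 990), (3, 30, 50, 900), (0, 20, 5, 100), (12, 8, 30, 150)],
    )
    def test_matches_brute_force_tail(self, table):
        p = _fisher_one_sided(*table)
        oracle = hypergeom_tail_brute(*table)
        assert p == pytest.approx(oracle, rel=1e-9)

    def test_strong_site_is_extreme(self):
        # 25/50 methylated vs gene background 10 non-converted / 990 converted
        p = _fisher_one_sided(25, 25, 10, 990)
        assert p < 1e-6


class TestCallSites:
    def _background_rows(self, gene="g1", n=20, coverage=50):
        return [
            ("chr1", 1000 + 10 * i, "+", gene, coverage, 0) for i in range(n)
        ]

    def test_coverage_filter_is_strict(self):
        rows = self._background_rows() + [("chr1", 5000, "+", "g1", 20, 10)]
        called = call_sites(site_frame(rows))
        assert not called.iloc[-1]["passes_filters"]

    def test_unmethylated_site_fails_c_cutoff(self):
        rows = self._background_rows() + [("chr1", 5000, "+", "g1", 100, 0)]
        called = call_sites(site_frame(rows))
        assert not called.iloc[-1]["passes_filters"]

    def test_min_rate_filter(self):
        rows = self._background_rows() + [("chr1", 5000, "+", "g1", 100, 5)]
        called = call_sites(site_frame(rows))
        assert not called.iloc[-1]["passes_filters"]  # rate 0.05 <= 0.1

    def test_methylated_site_called_against_gene_background(self):
        rows = self._background_rows(coverage=50) + [("chr1", 5000, "+", "g1", 50, 25)]
        called = call_sites(site_frame(rows))
        row = called.iloc[-1]
        assert row["passes_filters"]
        # oracle: site 25/25 vs background 1000 converted / 0 non-converted
        assert row["p"] == pytest.approx(hypergeom_tail_brute(25, 25, 0, 1000), rel=1e-9)
        assert row["q"] < 0.05

    def test_intergenic_site_uses_fallback_rate(self):
        rows = [("chr2", 100, "-", np.nan, 60, 30)]
        called = call_sites(site_frame(rows))
        row = called.iloc[0]
        assert row["passes_filters"]
        assert row["p"] == pytest.approx(hypergeom_tail_brute(30, 30, 100, 900), rel=1e-9)

    def test_background_excludes_tested_site(self):
        rows = [("chr1", 1000, "+", "g1", 100, 40), ("chr1", 1010, "+", "g1", 900, 10)]
        called = call_sites(site_frame(rows))
        # background for site 1 must be the OTHER site only: 890 conv / 10 nonconv
        assert called.iloc[0]["p"] == pytest.approx(
            hypergeom_tail_brute(40, 60, 10, 890), rel=1e-9
        )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError, match="exceeds coverage"):
            call_sites(site_frame([("chr1", 1, "+", "g1", 10, 11)]))


class TestConsensus:
    def _called(self, pos_sig):
        rows = [("chr1", 1000 + 10 * i, "+", "g1", 100, 0) for i in range(20)]
        rows += [("chr1", p, "+", "g1", 100, 50) for p in pos_sig]
        return call_sites(site_frame(rows))

    def test_site_missing_in_one_replicate_excluded(self):
        r1 = self._called([5000, 6000])
        r2 = self._called([5000])
        cons = consensus_sites([r1, r2])
        assert list(cons["pos_1based"]) == [5000]

    def test_single_replicate_condition(self):
        r1 = self._called([5000, 6000])
        cons = consensus_sites([r1])
        assert set(cons["pos_1based"]) == {5000, 6000}

    def test_zero_replicates_empty(self):
        assert consensus_sites([]).empty

    def test_fdr_threshold_respected(self):
        r1 = self._called([5000])
        cons = consensus_sites([r1], fdr=0.0)
        assert cons.empty


class TestDependentAndOverlap:
    def _cons(self, positions):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos_1based": positions,
                "strand": "+",
                "gene": [f"g{p}" for p in positions],
                "rate": 0.5,
                "coverage": 100.0,
                "n_replicates": 2,
            }
        )

    def test_identical_sets_empty(self):
        wt = self._cons([1, 2, 3])
        assert dependent_sites(wt, wt.copy()).empty

    def test_disjoint_sets_return_all_wt(self):
        wt, ko = self._cons([1, 2, 3]), self._cons([4, 5])
        dep = dependent_sites(wt, ko)
        assert set(dep["pos_1based"]) == {1, 2, 3}

    def test_overlap_counts_partition_union(self):
        dep = self._cons([1, 2, 3, 4])
        changes = pd.DataFrame(
            {
                "gene": ["g1", "g2", "g5", "g6", "g7"],
                "class": ["HL_up", "HL_and_S", "S_down", "HL_down", "none"],
            }
        )
        ov = overlap_with_dynamics(dep, changes)
        region_sum = (
            ov["m5c_only"] + ov["hl_only"] + ov["s_only"] + ov["m5c_hl"]
            + ov["m5c_s"] + ov["hl_s"] + ov["all_three"]
        )
        assert region_sum == ov["union"]
        assert 0.0 <= ov["dynamics_with_m5c_fraction"] <= 1.0

    def test_no_shared_genes_zero_overlap(self):
        dep = self._cons([9])
        changes = pd.DataFrame({"gene": ["gX"], "class": ["HL_up"]})
        ov = overlap_with_dynamics(dep, changes)
        assert ov["m5c_hl"] == ov["m5c_s"] == ov["all_three"] == 0

    def test_bed_export_is_zero_based_half_open(self):
        bed = sites_to_bed(self._cons([100]))
        assert bed.iloc[0]["start"] == 99 and bed.iloc[0]["end"] == 100


class TestFdrBehaviour:
    def test_null_sites_rarely_called(self):
        rng = np.random.default_rng(0)
        n = 2000
        coverage = rng.poisson(50, n) + 1
        nonconv = rng.binomial(coverage, 0.01)  # conversion efficiency 0.99, no methylation
        rows = site_frame(
            [
                ("chr1", 100 + 7 * i, "+", f"g{i % 100}", int(c), int(m))
                for i, (c, m) in enumerate(zip(coverage, nonconv))
            ]
        )
        called = call_sites(rows)
        false_rate = ((called["q"] < 0.05) & called["passes_filters"]).mean()
        assert false_rate <= 0.075

    def test_strong_sites_recovered_in_consensus(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(50):  # methylated sites, rate 0.5, coverage >= 50
            cov = 50 + int(rng.integers(0, 50))
            rows.append(("chr1", 10_000 + i, "+", f"g{i}", cov, int(rng.binomial(cov, 0.5))))
        for i in range(50):  # gene backgrounds
            for j in range(20):
                cov = 50
                rows.append(("chr2", 100_000 + 100 * i + j, "+", f"g{i}", cov,
                             int(rng.binomial(cov, 0.01))))
        calls = [call_sites(site_frame(rows))]
        cons = consensus_sites(calls)
        recovered = cons[cons["pos_1based"] >= 10_000]
        assert len(recovered) >= 49  # >= 98% single-replicate recall here
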