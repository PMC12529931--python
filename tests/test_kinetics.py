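"""Turnover kinetics: closed forms, normalization, dropout correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tucseq.kinetics import (
    LN2,
    DropoutCorrection,
    LabelingParams,
    degradation_rate,
    dropout_correction,
    halflife_to_ntr,
    ntr_to_halflife,
    quantify,
    size_factors,
    synthesis_rate,
)

PARAMS = LabelingParams(t=1.0)


class TestClosedForms:
    @pytest.mark.parametrize(
        "pi,expected_hl",
        [(0.5, 1.0), (0.75, 0.5), (1.0 - 2.0 ** (-0.5), 2.0)],
    )
    def test_halflife_values(self, pi, expected_hl):
        assert ntr_to_halflife(pi, PARAMS) == pytest.approx(expected_hl, abs=1e-9)

    def test_pulse_duration_scales(self):
        assert ntr_to_halflife(0.5, LabelingParams(t=2.0)) == pytest.approx(2.0)

    @given(st.floats(min_value=0.02, max_value=0.98))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, pi):
        assert halflife_to_ntr(ntr_to_halflife(pi, PARAMS), PARAMS) == pytest.approx(
            pi, abs=1e-10
        )

    def test_caps_and_flags(self):
        hl0, f0 = ntr_to_halflife(0.0, PARAMS, return_flags=True)
        hl1, f1 = ntr_to_halflife(1.0, PARAMS, return_flags=True)
        assert hl0 == 48.0 and f0
        assert hl1 == 0.05 and f1
        hl, f = ntr_to_halflife(0.5, PARAMS, return_flags=True)
        assert not f

    def test_invalid_pi_rejected(self):
        with pytest.raises(ValueError):
            ntr_to_halflife(1.2, PARAMS)
        with pytest.raises(ValueError):
            ntr_to_halflife(-0.1, PARAMS)

    def test_synthesis_formula(self):
        assert synthesis_rate(0.5, 0.0, PARAMS) == 0.0
        assert synthesis_rate(0.5, 100.0, PARAMS) == pytest.approx(100 * LN2)
        assert degradation_rate(0.5, PARAMS) == pytest.approx(LN2)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = size_factors(counts)
        assert np.allclose(sf / np.sqrt(sf.prod()), [1 / np.sqrt(2), np.sqrt(2)])

    def test_matches_literal_median_of_ratios(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, size=(200, 4)), columns=list("abcd"))
        sf = size_factors(counts)
        # literal reimplementation of the definition
        mat = counts.to_numpy(float)
        keep = (mat > 0).all(axis=1)
        geo = np.exp(np.mean(np.log(mat[keep]), axis=1))
        expected = [np.median(mat[keep, j] / geo) for j in range(4)]
        assert np.allclose(sf, expected, atol=1e-12)

    def test_all_zero_gene_rows_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="nonzero"):
            size_factors(counts)


def _dropout_fixture(rng, d, n_genes=400):
    """Counts + NTR for one labeled/unlabeled pair under known dropout."""
    pi = rng.uniform(0.05, 0.8, n_genes)
    base = rng.lognormal(np.log(500), 0.8, n_genes)
    unlabeled = rng.poisson(base).astype(float)
    labeled = rng.poisson(base * (1 - d * pi)).astype(float)
    pi_obs = pi * (1 - d) / (1 - d * pi)
    genes = pd.Index([f"G{i}" for i in range(n_genes)], name="gene")
    return (
        pd.Series(labeled, index=genes),
        pd.Series(pi_obs, index=genes),
        pd.Series(unlabeled, index=genes),
        pd.Series(pi, index=genes),
    )


class TestDropoutCorrection:
    def test_near_identity_without_dropout(self):
        rng = np.random.default_rng(1)
        labeled, pi_obs, unlabeled, pi_true = _dropout_fixture(rng, d=0.0)
        corr = dropout_correction(labeled, pi_obs, unlabeled)
        log2_change = np.log2(corr.counts / labeled)
        assert np.median(np.abs(log2_change)) < 0.05
        assert corr.dropout_strength < 0.05

    def test_recovers_true_ntr_under_dropout(self):
        rng = np.random.default_rng(2)
        labeled, pi_obs, unlabeled, pi_true = _dropout_fixture(rng, d=0.5)
        corr = dropout_correction(labeled, pi_obs, unlabeled)
        assert corr.dropout_strength == pytest.approx(0.5, abs=0.05)
        bias_before = np.median(pi_obs - pi_true)
        bias_after = np.median(corr.pi - pi_true)
        assert abs(bias_after) < abs(bias_before) / 3

    def test_post_correction_trend_flattened(self):
        rng = np.random.default_rng(3)
        labeled, pi_obs, unlabeled, _ = _dropout_fixture(rng, d=0.5)
        corr = dropout_correction(labeled, pi_obs, unlabeled)
        from scipy.stats import linregress

        before = linregress(pi_obs, np.log2((labeled + 0.5) / (unlabeled + 0.5))).slope
        after = linregress(pi_obs, np.log2((corr.counts + 0.5) / (unlabeled + 0.5))).slope
        assert abs(after) < abs(before) / 3

    def test_skipped_when_too_few_genes(self):
        rng = np.random.default_rng(4)
        labeled, pi_obs, unlabeled, _ = _dropout_fixture(rng, d=0.5, n_genes=10)
        with pytest.warns(UserWarning, match="skipped"):
            corr = dropout_correction(labeled, pi_obs, unlabeled)
        assert corr.dropout_strength == 0.0
        pd.testing.assert_series_equal(corr.counts, labeled.astype(float))


class TestQuantify:
    def _toy_inputs(self, pi_values=(0.5, 0.25), n_rep=2):
        genes = [f"G{i}" for i in range(len(pi_values))]
        design = pd.DataFrame(
            {
                "sample": [f"s{r}" for r in range(1, n_rep + 1)],
                "condition": "c1",
                "labeled": True,
            }
        )
        counts = pd.DataFrame(
            {f"s{r}": [1000, 2000] for r in range(1, n_rep + 1)},
            index=pd.Index(genes, name="gene"),
        )
        ntr = pd.DataFrame(
            {
                "gene": genes,
                "pi_map": list(pi_values),
                "alpha": [50.0] * len(genes),
                "beta": [50.0] * len(genes),
                "insufficient": False,
            }
        )
        return {f"s{r}": ntr for r in range(1, n_rep + 1)}, counts, design

    def test_identical_replicates_summary_equals_replicate(self):
        ntr_tables, counts, design = self._toy_inputs()
        table = quantify(ntr_tables, counts, design, PARAMS, dropout_correct=False)
        summ = table.condition_summary.set_index("gene")
        rep = table.replicates[table.replicates["sample"] == "s1"].set_index("gene")
        assert np.allclose(summ["HL_hours"], rep["HL_hours"])
        assert summ.loc["G0", "HL_hours"] == pytest.approx(1.0)

    def test_steady_state_conservation(self):
        ntr_tables, counts, design = self._toy_inputs()
        table = quantify(ntr_tables, counts, design, PARAMS, dropout_correct=False)
        s = table.condition_summary
        assert np.allclose(s["S_per_h"] * s["HL_hours"] / LN2, s["E_norm"], rtol=1e-9)

    def test_empty_input_gives_empty_table(self):
        table = quantify({}, pd.DataFrame(), pd.DataFrame(columns=["sample", "condition", "labeled"]), PARAMS)
        assert table.condition_summary.empty

    def test_missing_ntr_table_raises(self):
        ntr_tables, counts, design = self._toy_inputs()
        del ntr_tables["s2"]
        with pytest.raises(ValueError, match="missing NTR"):
            quantify(ntr_tables, counts, design, PARAMS)

    def test_combined_posterior_concentrates(self):
        ntr_tables, counts, design = self._toy_inputs()
        table = quantify(ntr_tables, counts, design, PARAMS, dropout_correct=False)
        post = table.posteriors.set_index("gene")
        # two replicates of Beta(50, 50) -> Beta(99, 99)
        assert post.loc["G0", "alpha"] == pytest.approx(99.0)
        assert post.loc["G0", "beta"] == pytest.approx(99.0)
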