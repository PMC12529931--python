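"""Model/Results interface over the estimation pipeline.

Two fitted-model pairs organize the statistical core:

* :class:`NtrMixtureModel` — the two-component binomial conversion
  mixture.  Built from labeled conversion histograms (plus optional
  unlabeled controls); ``fit()`` estimates the global rates (p_err from
  controls, p_new by EM) and every gene's NTR posterior.
* :class:`TurnoverModel` — steady-state turnover kinetics.  Built from
  per-sample NTR tables, the raw count matrix and the design table;
  ``fit()`` normalizes, corrects 4sU dropout and returns per-gene
  half-lives and synthesis rates with condition summaries, contrast
  classification, buffering and bootstrap methods on the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import buffering as _buffering
from . import diffdyn as _diffdyn
from . import features as _features
from . import kinetics as _kinetics
from . import mixture as _mixture

__all__ = ["NtrMixtureModel", "NtrMixtureResults", "TurnoverModel", "TurnoverResults"]


class NtrMixtureModel:
    """Two-component binomial mixture for new-to-total RNA ratios.

    Parameters
    ----------
    histograms : DataFrame (gene, n, k, count) or list of ConversionHistogram
        Conversion histograms of one labeled library.
    control : same, optional
        Unlabeled (no-4sU) histograms used to estimate the error rate.
    rates : GlobalRates, optional
        Fix both rates instead of estimating them.
    """

    def __init__(self, histograms, control=None, rates: _mixture.GlobalRates | None = None):
        if isinstance(histograms, pd.DataFrame):
            histograms = _mixture.histograms_from_frame(histograms)
        self.histograms: list[_mixture.ConversionHistogram] = list(histograms)
        self.control = control
        self.rates = rates

    @classmethod
    def from_frames(cls, labeled: pd.DataFrame, control: pd.DataFrame | None = None, **kw):
        return cls(labeled, control=control, **kw)

    def fit(
        self,
        grid_size: int = _mixture.DEFAULT_GRID_SIZE,
        min_reads: int = _mixture.DEFAULT_MIN_READS,
    ) -> "NtrMixtureResults":
        rates = self.rates
        if rates is None:
            if self.control is None:
                raise ValueError("need either fixed rates or control histograms")
            p_err = _mixture.estimate_error_rate(self.control)
            p_new = _mixture.estimate_conversion_rate(self.histograms, p_err)
            rates = _mixture.GlobalRates(p_err=p_err, p_new=p_new)
        estimates = {
            h.gene: _mixture.estimate_ntr(h, rates, grid_size=grid_size, min_reads=min_reads)
            for h in self.histograms
        }
        table = _mixture.ntr_table(self.histograms, rates, grid_size=grid_size, min_reads=min_reads)
        return NtrMixtureResults(model=self, rates=rates, estimates=estimates, table=table)


@dataclass
class NtrMixtureResults:
    """Fitted NTR mixture: global rates plus per-gene posteriors."""

    model: NtrMixtureModel
    rates: _mixture.GlobalRates
    estimates: dict[str, _mixture.NtrEstimate]
    table: pd.DataFrame

    def summary(self) -> str:
        ok = self.table[~self.table["insufficient"]]
        lines = [
            "NTR mixture model (two-component binomial)",
            f"  genes:            {len(self.table)} ({len(ok)} with sufficient reads)",
            f"  p_err:            {self.rates.p_err:.6f}",
            f"  p_new:            {self.rates.p_new:.6f}",
        ]
        if len(ok):
            lines += [
                f"  median NTR (MAP): {ok['pi_map'].median():.4f}",
                f"  median reads:     {ok['n_reads'].median():.0f}",
            ]
        return "\n".join(lines)


class TurnoverModel:
    """Steady-state one-compartment turnover fitted from NTRs and counts.

    Parameters
    ----------
    ntr_tables : dict sample -> DataFrame
        Per-labeled-sample NTR tables (columns gene, pi_map, alpha,
        beta, insufficient) as produced by :class:`NtrMixtureResults`.
    counts : DataFrame
        Raw genes x samples count matrix covering labeled and unlabeled
        libraries.
    design : DataFrame
        Columns sample, condition, labeled (bool).
    params : LabelingParams
        Pulse duration.
    """

    def __init__(
        self,
        ntr_tables: dict[str, pd.DataFrame],
        counts: pd.DataFrame,
        design: pd.DataFrame,
        params: _kinetics.LabelingParams = _kinetics.LabelingParams(),
        dropout_correct: bool = True,
        hl_min: float = _kinetics.DEFAULT_HL_MIN,
        hl_max: float = _kinetics.DEFAULT_HL_MAX,
    ):
        self.ntr_tables = ntr_tables
        self.counts = counts
        self.design = design
        self.params = params
        self.dropout_correct = dropout_correct
        self.hl_min = hl_min
        self.hl_max = hl_max

    def fit(self) -> "TurnoverResults":
        table = _kinetics.quantify(
            self.ntr_tables,
            self.counts,
            self.design,
            self.params,
            dropout_correct=self.dropout_correct,
            hl_min=self.hl_min,
            hl_max=self.hl_max,
        )
        return TurnoverResults(model=self, turnover=table)


@dataclass
class TurnoverResults:
    """Fitted turnover table with contrast, buffering and bootstrap methods."""

    model: TurnoverModel
    turnover: _kinetics.TurnoverTable

    @property
    def condition_summary(self) -> pd.DataFrame:
        return self.turnover.condition_summary

    @property
    def size_factors(self) -> pd.Series:
        return self.turnover.size_factors

    def conditions(self) -> list[str]:
        return sorted(self.turnover.condition_summary["condition"].unique())

    def compare(
        self,
        condition_a: str,
        condition_b: str,
        thresholds: _diffdyn.ClassifyThresholds = _diffdyn.ClassifyThresholds(),
        n_draws: int = 20_000,
        seed: int | None = 0,
    ) -> pd.DataFrame:
        """Per-gene change table for condition_b vs condition_a."""
        return _diffdyn.compare_conditions(
            self.turnover,
            self.model.counts,
            self.model.design,
            condition_a,
            condition_b,
            self.model.params,
            thresholds=thresholds,
            n_draws=n_draws,
            seed=seed,
        )

    def buffering(self, changes: pd.DataFrame) -> tuple[float, float, int]:
        """Spearman R of lfc_HL vs lfc_S among steady-state-stable genes."""
        return _buffering.buffering_correlation(changes)

    def bootstrap_shift(
        self,
        condition_a: str,
        condition_b: str,
        metric: str = "HL_hours",
        iterations: int = _buffering.DEFAULT_ITERATIONS,
        seed: int | None = 0,
    ) -> _buffering.BootstrapResult:
        """Bootstrap test of the median metric difference between conditions."""
        summ = self.turnover.condition_summary
        x = summ.loc[summ["condition"] == condition_a, metric].dropna().to_numpy()
        y = summ.loc[summ["condition"] == condition_b, metric].dropna().to_numpy()
        return _buffering.bootstrap_median_difference(x, y, iterations=iterations, seed=seed)

    def halflife_profiles(
        self, conditions: Iterable[str] | None = None
    ) -> pd.DataFrame:
        """Gene x condition half-life matrix (genes complete in all conditions)."""
        summ = self.turnover.condition_summary
        wide = summ.pivot(index="gene", columns="condition", values="HL_hours")
        if conditions is not None:
            wide = wide[list(conditions)]
        return wide.dropna()

    def cluster_halflives(
        self,
        conditions: Iterable[str] | None = None,
        k: int = _features.DEFAULT_K,
        seed: int | None = 0,
    ) -> _features.ClusterResult:
        return _features.zscore_cluster(self.halflife_profiles(conditions), k=k, seed=seed)

    def summary(self) -> str:
        summ = self.turnover.condition_summary
        lines = [
            "Steady-state turnover model",
            f"  pulse duration:  {self.model.params.t} h",
            f"  genes:           {summ['gene'].nunique()}",
            f"  conditions:      {', '.join(self.conditions())}",
            "  median half-life / synthesis by condition:",
        ]
        for cond, grp in summ.groupby("condition"):
            ok = grp[grp["flags"] != "insufficient"]
            lines.append(
                f"    {cond:>14}: HL = {ok['HL_hours'].median():6.2f} h, "
                f"S = {ok['S_per_h'].median():8.2f} /h  (n = {len(ok)})"
            )
        return "\n".join(lines)
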