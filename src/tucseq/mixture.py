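"""Two-component binomial mixture estimation of new-to-total RNA ratios.

After a 4sU pulse and T-to-C conversion chemistry, a read covering n
uridine positions shows k apparent T->C conversions.  Reads from RNA
synthesized during the pulse ("new") convert at rate p_new; pre-existing
("old") reads convert only at the error rate p_err.  For a gene with
new-to-total ratio pi, a read's likelihood is the mixture

    (1 - pi) * Binomial(k; n, p_err) + pi * Binomial(k; n, p_new).

This module estimates p_err from unlabeled control libraries, p_new by
EM over all labeled reads, and the per-gene pi by evaluating the mixture
likelihood on a uniform grid under a flat prior, returning the MAP, the
normalized grid posterior and a moment-matched Beta summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ConversionHistogram",
    "GlobalRates",
    "NtrEstimate",
    "estimate_error_rate",
    "estimate_conversion_rate",
    "estimate_ntr",
    "ntr_posterior_quantile",
    "histograms_from_frame",
]

ERROR_RATE_FLOOR = 1e-6
DEFAULT_GRID_SIZE = 1000
DEFAULT_MIN_READS = 10


@dataclass(frozen=True)
class GlobalRates:
    """Library-wide conversion rates of the two mixture components."""

    p_err: float
    p_new: float

    def __post_init__(self):
        if not 0.0 < self.p_err < self.p_new < 1.0:
            raise ValueError(
                f"rates must satisfy 0 < p_err < p_new < 1, got "
                f"p_err={self.p_err}, p_new={self.p_new}"
            )


@dataclass
class ConversionHistogram:
    """Per-gene counts of reads indexed by (n uridines, k conversions).

    The (n, k, count) triples are the sufficient statistic of the
    mixture likelihood; positional and sequence detail is deliberately
    absent.
    """

    gene: str
    n: np.ndarray
    k: np.ndarray
    count: np.ndarray

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=np.int64)
        self.k = np.asarray(self.k, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=np.int64)
        if not (self.n.shape == self.k.shape == self.count.shape):
            raise ValueError("n, k, count must have identical shapes")
        if np.any(self.k < 0) or np.any(self.k > self.n):
            raise ValueError("conversion counts must satisfy 0 <= k <= n")
        if np.any(self.count < 0):
            raise ValueError("read counts must be non-negative")

    @property
    def n_reads(self) -> int:
        return int(self.count.sum())

    @property
    def n_informative(self) -> int:
        """Reads with at least one uridine position."""
        return int(self.count[self.n > 0].sum())

    @classmethod
    def from_frame(cls, gene: str, frame: pd.DataFrame) -> "ConversionHistogram":
        return cls(
            gene=gene,
            n=frame["n"].to_numpy(),
            k=frame["k"].to_numpy(),
            count=frame["count"].to_numpy(),
        )


def histograms_from_frame(frame: pd.DataFrame) -> list[ConversionHistogram]:
    """Split a (gene, n, k, count) table into per-gene histograms."""
    return [
        ConversionHistogram.from_frame(gene, sub)
        for gene, sub in frame.groupby("gene", observed=True, sort=True)
    ]


def _pool(hists: Iterable[ConversionHistogram] | pd.DataFrame):
    if isinstance(hists, pd.DataFrame):
        return (
            hists["n"].to_numpy(np.int64),
            hists["k"].to_numpy(np.int64),
            hists["count"].to_numpy(np.int64),
        )
    ns, ks, cs = [], [], []
    for h in hists:
        ns.append(h.n)
        ks.append(h.k)
        cs.append(h.count)
    if not ns:
        return (np.array([], np.int64),) * 3
    return np.concatenate(ns), np.concatenate(ks), np.concatenate(cs)


def _dedupe(n, k, count):
    """Aggregate duplicate (n, k) classes to keep likelihood loops small."""
    keys = n * (n.max() + 2 if n.size else 1) + k
    uniq, inv = np.unique(keys, return_inverse=True)
    agg = np.zeros(uniq.size, dtype=np.int64)
    np.add.at(agg, inv, count)
    first = np.zeros(uniq.size, dtype=np.int64)
    first[inv[::-1]] = np.arange(n.size)[::-1]
    return n[first], k[first], agg


def estimate_error_rate(control: Iterable[ConversionHistogram] | pd.DataFrame) -> float:
    """Pooled T->C frequency of unlabeled (no-4sU) control libraries.

    Returns sum(k)/sum(n) over all reads; if no conversions were seen at
    all, returns a small floor (1e-6) with a warning rather than zero,
    so that downstream mixtures stay well defined.
    """
    n, k, count = _pool(control)
    total_u = int((n * count).sum())
    if total_u == 0:
        raise ValueError("control data contain no informative uridine positions")
    total_k = int((k * count).sum())
    if total_k == 0:
        warnings.warn(
            "no conversions observed in control data; returning floor 1e-6",
            stacklevel=2,
        )
        return ERROR_RATE_FLOOR
    return total_k / total_u


def _log_binom_pmf(k, n, p):
    return (
        special.gammaln(n + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n - k + 1)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )


def estimate_conversion_rate(
    labeled: Iterable[ConversionHistogram] | pd.DataFrame,
    p_err: float,
    tol: float = 1e-8,
    max_iter: int = 500,
    return_trace: bool = False,
):
    """EM estimate of the labeled-component conversion rate p_new.

    All labeled reads are pooled and modelled as a two-component
    binomial mixture with p_err fixed, p_new and the global mixing
    weight free.  The log-likelihood is non-decreasing per iteration;
    iteration stops when its change falls below *tol* or after
    *max_iter* rounds.
    """
    n, k, count = _dedupe(*_pool(labeled))
    if count.sum() == 0:
        raise ValueError("no labeled reads supplied")
    if int((count[k > 0]).sum()) == 0:
        raise ValueError("no reads with conversions; p_new is unidentifiable")

    log_old = _log_binom_pmf(k, n, p_err)
    p_new = max(5.0 * p_err, min(0.5, float((k * count).sum() / (n * count).sum()) * 2.0))
    w = 0.5
    trace: list[float] = []
    ll_prev = -np.inf
    for _ in range(max_iter):
        log_new = _log_binom_pmf(k, n, p_new)
        la = np.log(w) + log_new
        lb = np.log1p(-w) + log_old
        ll_read = np.logaddexp(la, lb)
        ll = float((count * ll_read).sum())
        trace.append(ll)
        resp = np.exp(la - ll_read)  # P(new | read class)
        wc = resp * count
        w = float(wc.sum() / count.sum())
        denom = float((wc * n).sum())
        if denom <= 0:
            break
        p_new = float(np.clip((wc * k).sum() / denom, p_err * 1.0001, 1.0 - 1e-9))
        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    if return_trace:
        return p_new, w, np.asarray(trace)
    return p_new


@dataclass
class NtrEstimate:
    """Posterior summary of a gene's new-to-total ratio.

    Carries the MAP on the evaluation grid, the normalized grid
    posterior (flat prior), a moment-matched Beta(alpha, beta) summary,
    and the read count the estimate rests on.  Genes below the read
    floor are flagged ``insufficient`` and excluded downstream.
    """

    gene: str
    pi_map: float
    alpha: float
    beta: float
    n_reads: int
    grid: np.ndarray | None = None
    posterior: np.ndarray | None = None
    log_likelihood: np.ndarray | None = field(default=None, repr=False)
    insufficient: bool = False

    @classmethod
    def from_beta(cls, gene: str, alpha: float, beta: float, n_reads: int = 0) -> "NtrEstimate":
        """Analytic construction from a Beta posterior (no grid stored)."""
        if alpha <= 0 or beta <= 0:
            raise ValueError("Beta parameters must be positive")
        mode = (alpha - 1) / (alpha + beta - 2) if alpha > 1 and beta > 1 else (
            0.0 if alpha <= 1 else 1.0
        )
        return cls(gene=gene, pi_map=mode, alpha=alpha, beta=beta, n_reads=n_reads)

    def quantile(self, q: float) -> float:
        return ntr_posterior_quantile(self, q)

    def credible_interval(self, q_lo: float = 0.05, q_hi: float = 0.95) -> tuple[float, float]:
        return self.quantile(q_lo), self.quantile(q_hi)

    def mean(self) -> float:
        if self.grid is not None:
            return float(np.trapezoid(self.grid * self.posterior, self.grid))
        return self.alpha / (self.alpha + self.beta)


def estimate_ntr(
    hist: ConversionHistogram,
    rates: GlobalRates,
    grid_size: int = DEFAULT_GRID_SIZE,
    min_reads: int = DEFAULT_MIN_READS,
) -> NtrEstimate:
    """Grid-posterior estimate of a gene's NTR under the binomial mixture.

    The likelihood L(pi) = prod over reads of
    [(1-pi) Binom(k; n, p_err) + pi Binom(k; n, p_new)] is evaluated in
    log space on a uniform grid over [0, 1] with a flat prior.  Returns
    the MAP (grid ties resolved to the smallest pi), the trapezoid-
    normalized posterior and its moment-matched Beta summary.  Genes
    with fewer than *min_reads* informative reads are flagged
    insufficient and carry no posterior.
    """
    if grid_size < 3:
        raise ValueError("grid_size must be at least 3")
    n, k, count = _dedupe(hist.n, hist.k, hist.count)
    informative = n > 0
    n, k, count = n[informative], k[informative], count[informative]
    n_inf = int(count.sum())
    if n_inf < min_reads:
        return NtrEstimate(
            gene=hist.gene,
            pi_map=float("nan"),
            alpha=float("nan"),
            beta=float("nan"),
            n_reads=n_inf,
            insufficient=True,
        )

    grid = np.linspace(0.0, 1.0, grid_size)
    log_old = _log_binom_pmf(k, n, rates.p_err)
    log_new = _log_binom_pmf(k, n, rates.p_new)
    with np.errstate(divide="ignore"):
        la = np.log1p(-grid)[:, None] + log_old[None, :]
        lb = np.log(grid)[:, None] + log_new[None, :]
    ll = np.logaddexp(la, lb) @ count.astype(float)

    i_map = int(np.argmax(ll))  # argmax returns the first (smallest-pi) maximizer
    dens = np.exp(ll - ll[i_map])
    z = np.trapezoid(dens, grid)
    dens = dens / z

    mean = float(np.trapezoid(grid * dens, grid))
    var = float(np.trapezoid((grid - mean) ** 2 * dens, grid))
    var = max(var, 1e-12)
    common = mean * (1.0 - mean) / var - 1.0
    common = max(common, 1e-6)
    alpha = max(mean * common, 1e-6)
    beta = max((1.0 - mean) * common, 1e-6)

    return NtrEstimate(
        gene=hist.gene,
        pi_map=float(grid[i_map]),
        alpha=alpha,
        beta=beta,
        n_reads=n_inf,
        grid=grid,
        posterior=dens,
        log_likelihood=ll,
    )


def ntr_posterior_quantile(est: NtrEstimate, q: float) -> float:
    """Quantile of the stored NTR posterior; monotone in q.

    Uses the grid posterior when available, otherwise the Beta summary.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    if est.insufficient:
        raise ValueError(f"gene {est.gene!r} has an insufficient-read estimate")
    if est.grid is None:
        return float(stats.beta.ppf(q, est.alpha, est.beta))
    dx = np.diff(est.grid)
    cdf = np.concatenate(
        [[0.0], np.cumsum(0.5 * dx * (est.posterior[1:] + est.posterior[:-1]))]
    )
    cdf /= cdf[-1]
    return float(np.interp(q, cdf, est.grid))


def ntr_table(
    hists: Iterable[ConversionHistogram],
    rates: GlobalRates,
    grid_size: int = DEFAULT_GRID_SIZE,
    min_reads: int = DEFAULT_MIN_READS,
) -> pd.DataFrame:
    """Estimate NTRs for many genes and tabulate the summaries."""
    rows = []
    for h in hists:
        est = estimate_ntr(h, rates, grid_size=grid_size, min_reads=min_reads)
        if est.insufficient:
            rows.append(
                {
                    "gene": est.gene,
                    "n_reads": est.n_reads,
                    "pi_map": np.nan,
                    "alpha": np.nan,
                    "beta": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "insufficient": True,
                }
            )
        else:
            lo, hi = est.credible_interval()
            rows.append(
                {
                    "gene": est.gene,
                    "n_reads": est.n_reads,
                    "pi_map": est.pi_map,
                    "alpha": est.alpha,
                    "beta": est.beta,
                    "ci_low": lo,
                    "ci_high": hi,
                    "insufficient": False,
                }
            )
    return pd.DataFrame(rows)
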