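"""Transcript buffering and bootstrap tests of distribution-level shifts.

Transcript buffering — compensatory, opposite-direction changes of
synthesis and stability that hold steady-state abundance constant — is
quantified as the Spearman correlation between per-gene half-life and
synthesis log2 fold changes among steady-state-stable genes.  Shifts of
whole HL/S distributions between genotypes are tested by bootstrap
resampling of the median difference (genes as the resampling unit) with
percentile confidence intervals at 95/99/99.9%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BootstrapResult",
    "buffering_correlation",
    "bootstrap_median_difference",
    "significance_stars",
]

DEFAULT_ITERATIONS = 20_000
MIN_STABLE_GENES = 10


def buffering_correlation(
    changes: pd.DataFrame,
    stable_only: bool = True,
    min_genes: int = MIN_STABLE_GENES,
) -> tuple[float, float, int]:
    """Spearman correlation of lfc_HL vs lfc_S among stable genes.

    Returns (R, two-sided p, n).  Ties get average ranks; the p-value
    uses the t-approximation (scipy's exact permutation path applies
    automatically only at trivially small n, where we fall back to it).
    A strongly negative R among genes whose steady-state abundance did
    not change is the buffering signature.
    """
    sub = changes
    if stable_only and "stable" in changes.columns:
        sub = changes[changes["stable"]]
    sub = sub.dropna(subset=["lfc_HL", "lfc_S"])
    n = len(sub)
    if n < min_genes:
        import warnings

        warnings.warn(f"only {n} stable genes; buffering correlation undefined", stacklevel=2)
        return float("nan"), float("nan"), n
    res = stats.spearmanr(sub["lfc_HL"], sub["lfc_S"])
    if n <= 9:
        p = _exact_spearman_pvalue(
            sub["lfc_HL"].to_numpy(), sub["lfc_S"].to_numpy(), float(res.statistic)
        )
        return float(res.statistic), p, n
    return float(res.statistic), float(res.pvalue), n


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray, observed: float) -> float:
    """Two-sided permutation p-value for Spearman's R at tiny n."""
    from itertools import permutations

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    count = 0
    total = 0
    sy = ry.std()
    for perm in permutations(ry):
        r = float(np.dot(rx, (np.asarray(perm) - ry.mean()) / sy)) / len(rx)
        total += 1
        if abs(r) >= abs(observed) - 1e-12:
            count += 1
    return count / total


@dataclass
class BootstrapResult:
    """Percentile-bootstrap summary of a median difference median(y) - median(x)."""

    observed: float
    iterations: int
    ci95: tuple[float, float]
    ci99: tuple[float, float]
    ci999: tuple[float, float]
    seed: int | None
    paired: bool = False

    @property
    def label(self) -> str:
        return significance_stars(self)

    def to_row(self) -> dict:
        return {
            "observed_diff": self.observed,
            "ci95_lo": self.ci95[0],
            "ci95_hi": self.ci95[1],
            "ci99_lo": self.ci99[0],
            "ci99_hi": self.ci99[1],
            "ci999_lo": self.ci999[0],
            "ci999_hi": self.ci999[1],
            "label": self.label,
            "iterations": self.iterations,
            "seed": self.seed,
        }


def _resampled_median_diffs(
    x: np.ndarray, y: np.ndarray, iterations: int, rng: np.random.Generator,
    paired: bool, chunk: int = 2000
) -> np.ndarray:
    diffs = np.empty(iterations)
    nx, ny = len(x), len(y)
    done = 0
    while done < iterations:
        b = min(chunk, iterations - done)
        if paired:
            idx = rng.integers(0, nx, size=(b, nx))
            diffs[done : done + b] = np.median(y[idx] - x[idx], axis=1)
        else:
            ix = rng.integers(0, nx, size=(b, nx))
            iy = rng.integers(0, ny, size=(b, ny))
            diffs[done : done + b] = np.median(y[iy], axis=1) - np.median(x[ix], axis=1)
        done += b
    return diffs


def bootstrap_median_difference(
    x,
    y,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = 0,
    paired: bool = False,
) -> BootstrapResult:
    """Bootstrap the difference of medians, median(y) - median(x).

    Each iteration resamples x and y independently with replacement at
    their original sizes (or resamples index pairs when *paired*);
    percentile intervals at 95/99/99.9% are reported together with a
    significance label based on which intervals exclude zero.
    Deterministic given *seed*.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("bootstrap inputs must be nonempty")
    if iterations < 1000:
        raise ValueError("use at least 1000 bootstrap iterations")
    if paired and x.size != y.size:
        raise ValueError("paired bootstrap requires equal-length inputs")
    rng = np.random.default_rng(seed)
    diffs = _resampled_median_diffs(x, y, iterations, rng, paired)
    observed = (
        float(np.median(y - x)) if paired else float(np.median(y) - np.median(x))
    )

    def ci(level: float) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        return (
            float(np.quantile(diffs, lo)),
            float(np.quantile(diffs, 1.0 - lo)),
        )

    return BootstrapResult(
        observed=observed,
        iterations=iterations,
        ci95=ci(0.95),
        ci99=ci(0.99),
        ci999=ci(0.999),
        seed=seed,
        paired=paired,
    )


def significance_stars(result: BootstrapResult) -> str:
    """Star label from nested percentile CIs.

    '***' if the 99.9% CI excludes zero, '**' for 99%, '*' for 95%,
    otherwise 'ns'.
    """

    def excludes_zero(ci: tuple[float, float]) -> bool:
        return ci[0] > 0.0 or ci[1] < 0.0

    if excludes_zero(result.ci999):
        return "***"
    if excludes_zero(result.ci99):
        return "**"
    if excludes_zero(result.ci95):
        return "*"
    return "ns"
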