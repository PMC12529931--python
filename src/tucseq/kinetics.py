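"""Steady-state turnover kinetics: NTR -> degradation rate, half-life, synthesis.

Under one-compartment steady-state turnover with degradation rate
delta, a pulse of duration t labels a fraction
pi = 1 - exp(-delta * t) of the transcript pool, so

    delta = -ln(1 - pi) / t,      HL = ln 2 / delta,      S = delta * E,

with E the (size-factor normalized) steady-state abundance.  This
module also implements median-of-ratios expression normalization and a
correction for 4sU dropout, the preferential loss of labeled molecules
that depresses both the counts and the observed NTR of short-lived
transcripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

LN2 = float(np.log(2.0))

DEFAULT_HL_MIN = 0.05  # hours; floor when pi -> 1
DEFAULT_HL_MAX = 48.0  # hours; cap when pi -> 0

__all__ = [
    "LabelingParams",
    "size_factors",
    "ntr_to_halflife",
    "halflife_to_ntr",
    "degradation_rate",
    "synthesis_rate",
    "dropout_correction",
    "DropoutCorrection",
    "quantify",
    "TurnoverTable",
]


@dataclass(frozen=True)
class LabelingParams:
    """Pulse-labeling parameters; ``t`` is the 4sU pulse duration in hours."""

    t: float = 1.0

    def __post_init__(self):
        if self.t <= 0:
            raise ValueError("pulse duration t must be positive")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes x samples count table).

    For genes nonzero in every sample, each sample's factor is the
    median of count / geometric-mean-across-samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors require at least two samples")
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene is nonzero in every sample")
    sub = mat[nonzero]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _validate_pi(pi):
    arr = np.asarray(pi, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("NTR values must lie in [0, 1]")
    return arr


def degradation_rate(
    pi,
    params: LabelingParams,
    hl_min: float = DEFAULT_HL_MIN,
    hl_max: float = DEFAULT_HL_MAX,
):
    """delta = -ln(1 - pi)/t, with pi near 0/1 capped via the HL bounds."""
    hl = ntr_to_halflife(pi, params, hl_min=hl_min, hl_max=hl_max)
    return LN2 / hl


def ntr_to_halflife(
    pi,
    params: LabelingParams,
    hl_min: float = DEFAULT_HL_MIN,
    hl_max: float = DEFAULT_HL_MAX,
    return_flags: bool = False,
):
    """Half-life from NTR: HL = -t ln 2 / ln(1 - pi).

    pi = 0 gives no information about decay within the pulse and is
    capped at *hl_max*; pi = 1 is floored at *hl_min*.  With
    ``return_flags`` a boolean array marks capped entries.
    """
    arr = _validate_pi(pi)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        hl = np.where(arr < 1.0, -params.t * LN2 / np.log1p(-arr), 0.0)
    flags = (hl > hl_max) | (hl < hl_min) | (arr == 0.0) | (arr == 1.0)
    hl = np.clip(hl, hl_min, hl_max)
    hl = np.where(arr == 0.0, hl_max, hl)
    if scalar:
        hl, flags = float(hl[0]), bool(flags[0])
    if return_flags:
        return hl, flags
    return hl


def halflife_to_ntr(hl, params: LabelingParams):
    """Inverse of :func:`ntr_to_halflife` on the uncapped domain."""
    hl = np.asarray(hl, dtype=float)
    out = 1.0 - np.exp(-LN2 * params.t / hl)
    return float(out) if out.ndim == 0 else out


def synthesis_rate(
    pi,
    e_norm,
    params: LabelingParams,
    hl_min: float = DEFAULT_HL_MIN,
    hl_max: float = DEFAULT_HL_MAX,
):
    """S = delta * E_norm; capped deltas propagate through."""
    e = np.asarray(e_norm, dtype=float)
    if np.any(e < 0):
        raise ValueError("normalized expression must be non-negative")
    return degradation_rate(pi, params, hl_min=hl_min, hl_max=hl_max) * e


@dataclass
class DropoutCorrection:
    """Outcome of the 4sU dropout correction for one labeled library."""

    counts: pd.Series  # corrected (float) counts
    pi: pd.Series  # corrected NTR
    dropout_strength: float  # fitted per-library loss rate of labeled molecules
    trend: pd.DataFrame  # gene, pi_obs, lfc_obs, f (anchored fitted trend)


def _pi_observed_to_true(pi_obs: np.ndarray, d: float) -> np.ndarray:
    """Invert the dropout bias: pi_obs = pi (1-d) / (1 - d pi)."""
    return pi_obs / (1.0 - d + d * pi_obs)


def fit_dropout_strength(
    pi_obs: np.ndarray,
    lfc: np.ndarray,
    weights: np.ndarray | None = None,
    d_max: float = 0.95,
) -> float:
    """Fit the per-library labeled-molecule loss rate d.

    If a fraction d of labeled (new) molecules is lost, a gene with true
    NTR pi keeps 1 - d*pi of its reads and its observed NTR is
    pi_obs = pi(1-d)/(1-d pi); the labeled/unlabeled log2 count ratio
    then follows a + log2(1 - d*pi) with a free normalization offset a.
    The single parameter d is fitted by least squares over genes, which
    is far more stable at small NTR than a nonparametric trend.
    """
    from scipy.optimize import minimize_scalar

    w = np.ones_like(lfc) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()

    def sse(d: float) -> float:
        pi_t = _pi_observed_to_true(pi_obs, d)
        pred = np.log2(1.0 - d * pi_t)
        resid = lfc - pred
        resid = resid - float(np.sum(w * resid))
        return float(np.sum(w * resid**2))

    res = minimize_scalar(sse, bounds=(0.0, d_max), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x) if res.fun < sse(0.0) else 0.0


def dropout_correction(
    counts_labeled: pd.Series,
    pi: pd.Series,
    counts_unlabeled: pd.Series,
    sf_labeled: float = 1.0,
    sf_unlabeled: float = 1.0,
    min_genes: int = 50,
) -> DropoutCorrection:
    """Correct labeled counts and NTRs for 4sU dropout.

    Dropout removes labeled (new) molecules, so a gene's labeled/
    unlabeled normalized count ratio decreases with its NTR.  The
    per-library loss rate d is fitted from that trend
    (:func:`fit_dropout_strength`); counts are then restored as
    c' = c / (1 - d*pi_true) and the NTR is inverted in closed form,
    pi' = pi / (1 - d + d*pi), which preserves the observed old-RNA
    quantity (the reads recovered by the correction are new-RNA reads).
    With d fitted near 0 the correction is a near-identity.
    """
    common = counts_labeled.index.intersection(counts_unlabeled.index)
    pi = pi.reindex(counts_labeled.index)
    norm_l = counts_labeled.loc[common] / sf_labeled
    norm_u = counts_unlabeled.loc[common] / sf_unlabeled
    ok = (norm_l > 0) & (norm_u > 0) & pi.loc[common].notna()
    genes = common[ok]
    if len(genes) < min_genes:
        warnings.warn(
            f"only {len(genes)} genes usable for dropout trend; correction skipped",
            stacklevel=2,
        )
        trend = pd.DataFrame({"gene": [], "pi_obs": [], "lfc_obs": [], "f": []})
        return DropoutCorrection(counts_labeled.astype(float), pi, 0.0, trend)

    x = pi.loc[genes].to_numpy(float)
    lfc = np.log2((norm_l.loc[genes] + 0.5) / (norm_u.loc[genes] + 0.5)).to_numpy()
    # inverse-variance weights for the log ratio of two counts
    w = 1.0 / (1.0 / norm_l.loc[genes].to_numpy() + 1.0 / norm_u.loc[genes].to_numpy())
    d = fit_dropout_strength(x, lfc, weights=w)

    all_pi = pi.to_numpy(float)
    pi_corr = np.where(np.isnan(all_pi), np.nan, _pi_observed_to_true(
        np.nan_to_num(all_pi, nan=0.0), d))
    pi_corr = np.clip(pi_corr, 0.0, 1.0)
    c = counts_labeled.to_numpy(float)
    retention = 1.0 - d * np.nan_to_num(pi_corr, nan=0.0)
    c_corr = c / retention

    f_fit = np.log2(1.0 - d * _pi_observed_to_true(x, d))
    trend = pd.DataFrame(
        {"gene": genes, "pi_obs": x, "lfc_obs": lfc, "f": f_fit}
    ).reset_index(drop=True)
    return DropoutCorrection(
        counts=pd.Series(c_corr, index=counts_labeled.index, name=counts_labeled.name),
        pi=pd.Series(pi_corr, index=counts_labeled.index, name="pi"),
        dropout_strength=d,
        trend=trend,
    )


@dataclass
class TurnoverTable:
    """Per-condition turnover summaries plus replicate-level detail.

    ``condition_summary`` holds one row per gene x condition with the
    median-across-replicates E_norm, delta (1/h), HL (h), S (units/h)
    and flags; ``replicates`` keeps per-sample values; ``posteriors``
    maps (gene, condition) to a combined Beta(alpha, beta) NTR posterior
    summary for downstream uncertainty propagation.
    """

    condition_summary: pd.DataFrame
    replicates: pd.DataFrame
    posteriors: pd.DataFrame  # gene, condition, alpha, beta
    size_factors: pd.Series


def quantify(
    ntr_tables: dict[str, pd.DataFrame],
    counts: pd.DataFrame,
    design: pd.DataFrame,
    params: LabelingParams,
    dropout_correct: bool = True,
    hl_min: float = DEFAULT_HL_MIN,
    hl_max: float = DEFAULT_HL_MAX,
) -> TurnoverTable:
    """Normalize, correct dropout, and compute per-gene HL and S.

    *ntr_tables* maps labeled sample names to NTR tables (columns gene,
    pi_map, alpha, beta, insufficient); *counts* is the genes x samples
    raw count matrix; *design* has columns sample, condition, labeled.
    Condition summaries are medians across labeled replicates.
    """
    if counts.empty:
        empty = pd.DataFrame(
            columns=["gene", "condition", "E_norm", "delta", "HL_hours", "S_per_h", "flags"]
        )
        return TurnoverTable(empty, empty.copy(), pd.DataFrame(), pd.Series(dtype=float))
    sf = size_factors(counts)
    labeled = design[design["labeled"]]
    missing = set(labeled["sample"]) - set(ntr_tables)
    if missing:
        raise ValueError(f"missing NTR tables for samples: {sorted(missing)}")

    rep_rows = []
    for _, row in labeled.iterrows():
        sample, cond = row["sample"], row["condition"]
        ntab = ntr_tables[sample].set_index("gene")
        c = counts[sample]
        pi = ntab["pi_map"].reindex(c.index)
        alpha = ntab["alpha"].reindex(c.index)
        beta = ntab["beta"].reindex(c.index)

        ctrl = design[(design["condition"] == cond) & (~design["labeled"])]["sample"]
        corrected = False
        c_use, pi_use = c.astype(float), pi
        if dropout_correct:
            if len(ctrl) == 0:
                warnings.warn(
                    f"no unlabeled control for condition {cond!r}; "
                    "dropout correction skipped",
                    stacklevel=2,
                )
            else:
                ctrl_norm = (counts[list(ctrl)] / sf[list(ctrl)]).mean(axis=1)
                corr = dropout_correction(c, pi, ctrl_norm, sf_labeled=sf[sample])
                c_use, pi_use = corr.counts, corr.pi
                # shift the Beta posterior mean to the corrected NTR,
                # keeping the concentration (effective read support)
                conc = alpha + beta
                mean_corr = pi_use.clip(1e-6, 1.0 - 1e-6)
                alpha = mean_corr * conc
                beta = (1.0 - mean_corr) * conc
                corrected = True

        e_norm = c_use / sf[sample]
        ok = pi_use.notna()
        hl, flags = ntr_to_halflife(
            pi_use.fillna(0.0).to_numpy(), params, hl_min, hl_max, return_flags=True
        )
        delta = LN2 / hl
        s = delta * e_norm.to_numpy()
        rep_rows.append(
            pd.DataFrame(
                {
                    "gene": c.index,
                    "sample": sample,
                    "condition": cond,
                    "E_norm": e_norm.to_numpy(),
                    "pi": pi_use.to_numpy(float),
                    "alpha": alpha.to_numpy(float),
                    "beta": beta.to_numpy(float),
                    "delta": np.where(ok, delta, np.nan),
                    "HL_hours": np.where(ok, hl, np.nan),
                    "S_per_h": np.where(ok, s, np.nan),
                    "capped": np.where(ok, flags, False),
                    "insufficient": ~ok.to_numpy(),
                    "dropout_corrected": corrected,
                }
            )
        )
    replicates = pd.concat(rep_rows, ignore_index=True)

    def _summarize(group: pd.DataFrame) -> pd.Series:
        hl_med = group["HL_hours"].median()
        return pd.Series(
            {
                "E_norm": group["E_norm"].median(),
                "HL_hours": hl_med,
                "delta": LN2 / hl_med if hl_med and np.isfinite(hl_med) else np.nan,
                "S_per_h": group["S_per_h"].median(),
                "n_replicates": int(group["HL_hours"].notna().sum()),
                "capped": bool(group["capped"].any()),
                "insufficient": bool(group["insufficient"].all()),
            }
        )

    with warnings.catch_warnings():
        # all-NaN gene/condition groups (insufficient reads) are expected
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        warnings.filterwarnings("ignore", message="All-NaN slice encountered")
        condition_summary = (
            replicates.groupby(["gene", "condition"], observed=True)
            .apply(_summarize, include_groups=False)
            .reset_index()
        )
    condition_summary["flags"] = np.select(
        [condition_summary["insufficient"], condition_summary["capped"]],
        ["insufficient", "capped"],
        default="",
    )

    # combine replicate Beta posteriors: with a flat prior, the product of
    # replicate posteriors is Beta(sum alpha - (R-1), sum beta - (R-1))
    post = (
        replicates.dropna(subset=["alpha", "beta"])
        .groupby(["gene", "condition"], observed=True)
        .agg(alpha=("alpha", "sum"), beta=("beta", "sum"), r=("alpha", "size"))
        .reset_index()
    )
    post["alpha"] = (post["alpha"] - (post["r"] - 1)).clip(lower=1e-6)
    post["beta"] = (post["beta"] - (post["r"] - 1)).clip(lower=1e-6)
    posteriors = post.drop(columns="r")

    return TurnoverTable(condition_summary, replicates, posteriors, sf)
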