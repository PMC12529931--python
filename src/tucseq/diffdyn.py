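"""Classification of turnover changes between conditions.

A gene's half-life (or synthesis rate) is called changed between two
conditions when both a magnitude criterion |log2 fc| > 1 and a
confidence criterion on the posterior of the change hold.  The latter
is a signed region-of-practical-equivalence (ROPE) statistic: with
Delta the posterior of log2(HL_B / HL_A) and w a practical-equivalence
half-width, the statistic is P(Delta > w) - P(Delta < -w), which
approaches +/-1 only when the posterior mass lies confidently on one
side of the equivalence region.  Steady-state differential expression
uses a Wald-type test on log2 normalized counts with BH correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .kinetics import LN2, LabelingParams, ntr_to_halflife

__all__ = [
    "ClassifyThresholds",
    "log2fc",
    "rope_statistic",
    "rope_table",
    "classify_turnover_change",
    "steady_state_de",
    "bh_adjust",
    "deg_decomposition",
    "compare_conditions",
]

DEFAULT_ROPE_WIDTH = 0.25  # log2 units
DEFAULT_ROPE_THRESHOLD = 0.45
DEFAULT_LFC_THRESHOLD = 1.0

CLASSES = ("HL_up", "HL_down", "S_up", "S_down", "HL_and_S", "none")


@dataclass(frozen=True)
class ClassifyThresholds:
    lfc: float = DEFAULT_LFC_THRESHOLD
    rope: float = DEFAULT_ROPE_THRESHOLD
    rope_width: float = DEFAULT_ROPE_WIDTH


def log2fc(a, b, pseudocount: float = 0.0):
    """log2((b + pseudocount) / (a + pseudocount)).

    Use pseudocount 0.5 for raw counts; HL/S values are already positive
    and need at most a tiny regularizer (default used by callers: 1e-8).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("log2fc inputs must be non-negative")
    out = np.log2(b + pseudocount) - np.log2(a + pseudocount)
    return float(out) if out.ndim == 0 else out


def _signed_band_mass(delta: np.ndarray, w: float) -> np.ndarray:
    """P(delta > w) - P(delta < -w) along the last (draws) axis."""
    return (delta > w).mean(axis=-1) - (delta < -w).mean(axis=-1)


def rope_table(
    alpha_a,
    beta_a,
    alpha_b,
    beta_b,
    params: LabelingParams,
    w: float = DEFAULT_ROPE_WIDTH,
    offset=0.0,
    invert: bool = False,
    n_draws: int = 100_000,
    rng=None,
    chunk: int = 200,
) -> np.ndarray:
    """Vectorized signed ROPE statistics for many genes at once.

    NTR posteriors Beta(alpha, beta) are propagated by Monte Carlo
    through the half-life transform; Delta = log2(HL_B/HL_A) + offset.
    With ``invert`` the degradation-rate ratio (i.e. -log2 HL ratio) is
    used instead, which combined with an expression offset yields the
    synthesis-rate statistic log2(S_B/S_A) = log2(dB/dA) + log2(EB/EA).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    alpha_a, beta_a, alpha_b, beta_b = (
        np.atleast_1d(np.asarray(x, dtype=float)) for x in (alpha_a, beta_a, alpha_b, beta_b)
    )
    offset = np.broadcast_to(np.asarray(offset, dtype=float), alpha_a.shape).copy()
    out = np.full(alpha_a.shape, np.nan)
    valid = np.isfinite(alpha_a) & np.isfinite(beta_a) & np.isfinite(alpha_b) & np.isfinite(beta_b)
    idx = np.flatnonzero(valid)
    sign = -1.0 if invert else 1.0
    # clip NTR draws to the measurable half-life window [hl_min, hl_max]
    from .kinetics import DEFAULT_HL_MAX, DEFAULT_HL_MIN, halflife_to_ntr

    pi_lo = halflife_to_ntr(DEFAULT_HL_MAX, params)
    pi_hi = halflife_to_ntr(DEFAULT_HL_MIN, params)
    for start in range(0, idx.size, chunk):
        sel = idx[start : start + chunk]
        pa = rng.beta(alpha_a[sel, None], beta_a[sel, None], size=(sel.size, n_draws))
        pb = rng.beta(alpha_b[sel, None], beta_b[sel, None], size=(sel.size, n_draws))
        np.clip(pa, pi_lo, pi_hi, out=pa)
        np.clip(pb, pi_lo, pi_hi, out=pb)
        # log2(HL_B/HL_A) = log2(log(1-pi_A)/log(1-pi_B))
        delta = sign * np.log2(np.log1p(-pa) / np.log1p(-pb)) + offset[sel, None]
        out[sel] = _signed_band_mass(delta, w)
    return out


def rope_statistic(
    posterior_a: tuple[float, float],
    posterior_b: tuple[float, float],
    params: LabelingParams,
    w: float = DEFAULT_ROPE_WIDTH,
    n_draws: int = 100_000,
    rng=None,
) -> float:
    """Signed ROPE statistic for one gene's half-life change.

    *posterior_a*, *posterior_b* are Beta(alpha, beta) NTR posterior
    summaries for the two conditions.
    """
    return float(
        rope_table(
            posterior_a[0],
            posterior_a[1],
            posterior_b[0],
            posterior_b[1],
            params,
            w=w,
            n_draws=n_draws,
            rng=rng,
        )[0]
    )


def classify_turnover_change(
    lfc_hl: float,
    rope_hl: float,
    lfc_s: float,
    rope_s: float,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> str:
    """Apply the joint magnitude + ROPE gate to one gene.

    HL changed iff |lfc_HL| > lfc-threshold AND |rope_HL| > rope-threshold
    (sign of lfc gives up/down); same for S; both changed -> HL_and_S.
    Missing ROPE statistics (NaN) fail the gate.
    """
    hl_changed = (
        np.isfinite(lfc_hl)
        and np.isfinite(rope_hl)
        and abs(lfc_hl) > thresholds.lfc
        and abs(rope_hl) > thresholds.rope
    )
    s_changed = (
        np.isfinite(lfc_s)
        and np.isfinite(rope_s)
        and abs(lfc_s) > thresholds.lfc
        and abs(rope_s) > thresholds.rope
    )
    if hl_changed and s_changed:
        return "HL_and_S"
    if hl_changed:
        return "HL_up" if lfc_hl > 0 else "HL_down"
    if s_changed:
        return "S_up" if lfc_s > 0 else "S_down"
    return "none"


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def steady_state_de(
    counts: pd.DataFrame,
    factors: pd.Series,
    samples_a: list[str],
    samples_b: list[str],
    pseudocount: float = 0.5,
    var_floor: float = 1e-3,
) -> pd.DataFrame:
    """Wald-type differential expression on log2 normalized counts.

    Per gene: lfc_E = log2 of normalized mean counts (with pseudocount),
    Wald statistic = difference of mean log2 normalized counts divided
    by the pooled standard error (with a small variance floor), compared
    against a Student-t reference with n_A + n_B - 2 degrees of freedom,
    then BH-adjusted.  Single-replicate conditions yield lfc only.
    """
    norm = counts / factors
    a = np.log2(norm[samples_a] + pseudocount)
    b = np.log2(norm[samples_b] + pseudocount)
    na, nb = len(samples_a), len(samples_b)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    lfc = np.log2(norm[samples_b].mean(axis=1) + pseudocount) - np.log2(
        norm[samples_a].mean(axis=1) + pseudocount
    )
    out = pd.DataFrame({"gene": counts.index, "lfc_E": lfc.to_numpy()})
    if na < 2 or nb < 2:
        out["de_p"] = np.nan
        out["de_q"] = np.nan
        return out
    df_resid = na + nb - 2
    pooled_var = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / df_resid
    pooled_var = np.maximum(pooled_var, var_floor)
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    wald = (mean_b - mean_a) / se
    p = 2.0 * stats.t.sf(np.abs(wald), df_resid)
    out["de_stat"] = wald.to_numpy()
    out["de_p"] = p
    out["de_q"] = bh_adjust(p)
    return out


def deg_decomposition(
    changes: pd.DataFrame,
    lfc_threshold: float = 1.0,
    fdr: float = 0.05,
) -> pd.Series:
    """Partition DEGs by which turnover parameter changed.

    DEGs are genes with |lfc_E| > *lfc_threshold* and de_q < *fdr*;
    fractions over {S_only, HL_only, both, neither} sum to 1.
    """
    deg = changes[
        (changes["lfc_E"].abs() > lfc_threshold) & (changes["de_q"] < fdr)
    ]
    if deg.empty:
        warnings.warn("empty DEG set; decomposition fractions are all zero", stacklevel=2)
        return pd.Series(
            {"S_only": 0.0, "HL_only": 0.0, "both": 0.0, "neither": 0.0, "n_deg": 0}
        )
    cls = deg["class"]
    n = len(deg)
    return pd.Series(
        {
            "S_only": float(cls.isin(["S_up", "S_down"]).sum()) / n,
            "HL_only": float(cls.isin(["HL_up", "HL_down"]).sum()) / n,
            "both": float((cls == "HL_and_S").sum()) / n,
            "neither": float((cls == "none").sum()) / n,
            "n_deg": n,
        }
    )


def compare_conditions(
    turnover,
    counts: pd.DataFrame,
    design: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    params: LabelingParams,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
    n_draws: int = 20_000,
    seed: int | None = 0,
    stable_lfc: float = 1.0,
    stable_fdr: float = 0.05,
) -> pd.DataFrame:
    """Full per-gene change table for a contrast (B vs A).

    Combines HL/S log2 fold changes from condition summaries, ROPE
    statistics propagated from the combined NTR Beta posteriors, and
    steady-state DE from the labeled count matrix.  The ``stable`` flag
    marks genes with no practically relevant steady-state change
    (|lfc_E| < 1 and de_q > 0.05) — the gene set on which transcript
    buffering is assessed.
    """
    summ = turnover.condition_summary
    ta = summ[summ["condition"] == condition_a].set_index("gene")
    tb = summ[summ["condition"] == condition_b].set_index("gene")
    genes = ta.index.intersection(tb.index)
    ta, tb = ta.loc[genes], tb.loc[genes]

    lfc_hl = log2fc(ta["HL_hours"].to_numpy(), tb["HL_hours"].to_numpy(), 1e-8)
    lfc_s = log2fc(ta["S_per_h"].to_numpy() + 1e-8, tb["S_per_h"].to_numpy() + 1e-8)

    post = turnover.posteriors
    pa = post[post["condition"] == condition_a].set_index("gene").reindex(genes)
    pb = post[post["condition"] == condition_b].set_index("gene").reindex(genes)
    rng = np.random.default_rng(seed)
    rope_hl = rope_table(
        pa["alpha"], pa["beta"], pb["alpha"], pb["beta"],
        params, w=thresholds.rope_width, n_draws=n_draws, rng=rng,
    )
    e_offset = log2fc(ta["E_norm"].to_numpy() + 1e-8, tb["E_norm"].to_numpy() + 1e-8)
    rope_s = rope_table(
        pa["alpha"], pa["beta"], pb["alpha"], pb["beta"],
        params, w=thresholds.rope_width, offset=e_offset, invert=True,
        n_draws=n_draws, rng=rng,
    )

    labeled = design[design["labeled"]]
    sa = list(labeled[labeled["condition"] == condition_a]["sample"])
    sb = list(labeled[labeled["condition"] == condition_b]["sample"])
    from .kinetics import size_factors as _sf

    de = steady_state_de(counts[sa + sb], _sf(counts)[sa + sb], sa, sb).set_index("gene")
    de = de.reindex(genes)

    insufficient = (ta["flags"] == "insufficient") | (tb["flags"] == "insufficient")
    records = pd.DataFrame(
        {
            "gene": genes,
            "contrast": f"{condition_b}_vs_{condition_a}",
            "lfc_HL": np.where(insufficient, np.nan, lfc_hl),
            "rope_HL": np.where(insufficient, np.nan, rope_hl),
            "lfc_S": np.where(insufficient, np.nan, lfc_s),
            "rope_S": np.where(insufficient, np.nan, rope_s),
            "lfc_E": de["lfc_E"].to_numpy(),
            "de_p": de["de_p"].to_numpy(),
            "de_q": de["de_q"].to_numpy(),
        }
    )
    records["class"] = [
        classify_turnover_change(h, rh, s, rs, thresholds)
        for h, rh, s, rs in zip(
            records["lfc_HL"], records["rope_HL"], records["lfc_S"], records["rope_S"]
        )
    ]
    records["stable"] = (records["lfc_E"].abs() < stable_lfc) & (
        records["de_q"].fillna(1.0) > stable_fdr
    )
    return records.reset_index(drop=True)
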