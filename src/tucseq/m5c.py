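"""m5C candidate-site calling from RNA bisulfite sequencing site tables.

5-methylcytosine resists bisulfite-driven C->U conversion, so cytosines
that stay non-converted above the background non-conversion rate mark
candidate m5C sites.  Sites are filtered (coverage > 20, at least 3
non-converted reads, methylation rate > 0.1), tested one-sided against
the gene-specific conversion background with Fisher's exact test, and
BH-adjusted.  Consensus sites must pass in every replicate of a
condition at FDR < 0.05; Nsun2-dependent sites are the consensus sites
lost in the knockout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffdyn import bh_adjust

__all__ = [
    "SiteFilters",
    "ConversionContext",
    "call_sites",
    "consensus_sites",
    "dependent_sites",
    "overlap_with_dynamics",
    "sites_to_bed",
]

SITE_KEY = ["chrom", "pos_1based", "strand"]


@dataclass(frozen=True)
class SiteFilters:
    """Site-level filters mirroring the upstream caller's conventions.

    Coverage is strictly greater-than; duplicate and signal-to-noise
    filters act on alignment-level information absent from site tables
    and are assumed pre-applied upstream.
    """

    min_coverage: int = 20  # strictly > 20 reads
    c_cutoff: int = 3  # minimum non-converted reads
    min_rate: float = 0.1  # strictly > 0.1
    fallback_conversion_rate: float = 0.9  # for sites without a gene background
    fallback_pseudo_total: int = 1000


@dataclass
class ConversionContext:
    """Per-gene bisulfite conversion background.

    ``totals`` maps gene -> (converted, non_converted) summed over all
    of the gene's assayed cytosines; when a site is tested, its own
    counts are subtracted so the background excludes the tested site.
    Intergenic sites fall back to a conservative fixed conversion rate.
    """

    totals: pd.DataFrame  # index gene, columns converted, non_converted
    fallback_conversion_rate: float = 0.9
    fallback_pseudo_total: int = 1000

    @classmethod
    def from_sites(
        cls,
        sites: pd.DataFrame,
        fallback_conversion_rate: float = 0.9,
        fallback_pseudo_total: int = 1000,
    ) -> "ConversionContext":
        with_gene = sites.dropna(subset=["gene"])
        totals = with_gene.groupby("gene", observed=True).agg(
            coverage=("coverage", "sum"), non_converted=("non_converted", "sum")
        )
        totals["converted"] = totals["coverage"] - totals["non_converted"]
        return cls(
            totals=totals[["converted", "non_converted"]],
            fallback_conversion_rate=fallback_conversion_rate,
            fallback_pseudo_total=fallback_pseudo_total,
        )

    def background_for(self, gene, site_coverage: int, site_non_converted: int):
        """(converted, non_converted) background excluding the tested site."""
        if gene is not None and not (isinstance(gene, float) and np.isnan(gene)) and gene in self.totals.index:
            conv = int(self.totals.loc[gene, "converted"]) - (site_coverage - site_non_converted)
            nonconv = int(self.totals.loc[gene, "non_converted"]) - site_non_converted
            if conv > 0 and nonconv >= 0:
                return conv, nonconv
            return None
        nonconv = int(round(self.fallback_pseudo_total * (1.0 - self.fallback_conversion_rate)))
        return self.fallback_pseudo_total - nonconv, nonconv


def call_sites(
    sites: pd.DataFrame,
    context: ConversionContext | None = None,
    filters: SiteFilters = SiteFilters(),
) -> pd.DataFrame:
    """Filter and test candidate m5C sites of one replicate.

    Returns the input annotated with rate, passes_filters, one-sided
    Fisher p (enrichment of non-conversion over the gene background)
    and BH q over the tested sites.  The 2x2 table per site is
    [[site_non_converted, site_converted],
     [background_non_converted, background_converted]], the background
    being the gene's assayed-C totals excluding the tested site, or a
    conservative fallback conversion rate for intergenic sites.
    """
    out = sites.copy()
    if np.any(out["non_converted"] > out["coverage"]):
        raise ValueError("non_converted exceeds coverage in site table")
    if context is None:
        context = ConversionContext.from_sites(
            out, filters.fallback_conversion_rate, filters.fallback_pseudo_total
        )
    out["rate"] = out["non_converted"] / out["coverage"]
    out["passes_filters"] = (
        (out["coverage"] > filters.min_coverage)
        & (out["non_converted"] >= filters.c_cutoff)
        & (out["rate"] > filters.min_rate)
    )
    p = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples(index=False)):
        if not row.passes_filters:
            continue
        bg = context.background_for(row.gene, int(row.coverage), int(row.non_converted))
        if bg is None:
            warnings.warn(
                f"no usable conversion background for site at "
                f"{row.chrom}:{row.pos_1based}; site skipped",
                stacklevel=2,
            )
            continue
        bg_conv, bg_nonconv = bg
        p[i] = _fisher_one_sided(
            int(row.non_converted),
            int(row.coverage) - int(row.non_converted),
            bg_nonconv,
            bg_conv,
        )
    out["p"] = p
    q = np.full(len(out), np.nan)
    tested = np.isfinite(p)
    if tested.any():
        q[tested] = bh_adjust(p[tested])
    out["q"] = q
    return out


def _fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher's exact test P(X >= a) for table [[a, b], [c, d]].

    Computed as the hypergeometric upper tail with population a+b+c+d,
    a+c successes and a+b draws.
    """
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def consensus_sites(
    replicate_calls: list[pd.DataFrame],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Sites significant in every replicate of a condition.

    A site (chrom, pos, strand) is kept iff it passes filters and has
    q < *fdr* in each supplied replicate; a single-replicate condition
    reduces to that replicate's significant sites.  Reported rate and
    coverage are means across replicates.
    """
    if not replicate_calls:
        return pd.DataFrame(columns=SITE_KEY + ["gene", "rate", "coverage", "n_replicates"])
    sig = []
    for calls in replicate_calls:
        keep = calls[(calls["passes_filters"]) & (calls["q"] < fdr)]
        sig.append(keep.set_index(SITE_KEY))
    common = sig[0].index
    for s in sig[1:]:
        common = common.intersection(s.index)
    if len(common) == 0:
        return pd.DataFrame(columns=SITE_KEY + ["gene", "rate", "coverage", "n_replicates"])
    rows = []
    for key in common:
        rates = [float(s.loc[key, "rate"]) for s in sig]
        covs = [float(s.loc[key, "coverage"]) for s in sig]
        gene = sig[0].loc[key, "gene"]
        rows.append(
            dict(
                zip(SITE_KEY, key),
                gene=gene,
                rate=float(np.mean(rates)),
                coverage=float(np.mean(covs)),
                n_replicates=len(sig),
            )
        )
    return pd.DataFrame(rows).sort_values(SITE_KEY, ignore_index=True)


def dependent_sites(consensus_wt: pd.DataFrame, consensus_ko: pd.DataFrame) -> pd.DataFrame:
    """Methyltransferase-dependent sites: consensus(WT) minus consensus(KO)."""
    if consensus_wt.empty:
        return consensus_wt.copy()
    wt = consensus_wt.set_index(SITE_KEY)
    ko_index = (
        consensus_ko.set_index(SITE_KEY).index
        if not consensus_ko.empty
        else pd.MultiIndex.from_arrays([[], [], []], names=SITE_KEY)
    )
    kept = wt.loc[~wt.index.isin(ko_index)]
    return kept.reset_index()


def overlap_with_dynamics(
    dependent: pd.DataFrame,
    changes: pd.DataFrame,
) -> dict:
    """Three-way gene-level overlap of m5C, altered-HL and altered-S sets.

    Returns the seven Venn region counts plus the fraction of
    dynamics-altered genes (any HL or S change) carrying a dependent
    m5C site.
    """
    m5c_genes = set(dependent["gene"].dropna()) if len(dependent) else set()
    hl_genes = set(changes.loc[changes["class"].isin(["HL_up", "HL_down", "HL_and_S"]), "gene"])
    s_genes = set(changes.loc[changes["class"].isin(["S_up", "S_down", "HL_and_S"]), "gene"])
    a, b, c = m5c_genes, hl_genes, s_genes
    regions = {
        "m5c_only": len(a - b - c),
        "hl_only": len(b - a - c),
        "s_only": len(c - a - b),
        "m5c_hl": len((a & b) - c),
        "m5c_s": len((a & c) - b),
        "hl_s": len((b & c) - a),
        "all_three": len(a & b & c),
    }
    dynamics = b | c
    regions["n_m5c"] = len(a)
    regions["n_hl"] = len(b)
    regions["n_s"] = len(c)
    regions["union"] = len(a | b | c)
    regions["dynamics_with_m5c_fraction"] = (
        len(dynamics & a) / len(dynamics) if dynamics else 0.0
    )
    return regions


def sites_to_bed(sites: pd.DataFrame) -> pd.DataFrame:
    """Convert 1-based site coordinates to 0-based half-open BED records."""
    return pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["pos_1based"] - 1,
            "end": sites["pos_1based"],
            "name": sites.get("gene", pd.Series(["."] * len(sites))).fillna("."),
            "score": 0,
            "strand": sites["strand"],
        }
    )
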