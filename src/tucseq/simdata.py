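"""Ground-truthed simulator for 3'-end TUC-seq conversion data and BS-seq tables.

The generator emulates a 4sU pulse-labeling experiment read out by
T-to-C conversion sequencing: per-condition turnover parameters
(half-life HL, synthesis rate S, steady-state abundance E = S*HL/ln2)
are drawn with a configurable transcript-buffering structure, read-level
conversion data are sampled under the two-component binomial model the
estimator assumes, and RNA bisulfite site tables are produced with known
per-cytosine methylation rates.  Everything is deterministic given the
configured seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

LN2 = float(np.log(2.0))

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_truth",
    "simulate_conversion_reads",
    "apply_dropout",
    "simulate_bisulfite",
    "simulate_dataset",
    "sample_name",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study design.

    Defaults describe a 1 h 4sU pulse read out on a 3'-end library:
    low conversion rates, log-normal library-size variation, half-lives
    spanning 0.5-16 h, and a buffered gene fraction whose HL/S changes
    are anticorrelated while steady-state abundance stays within a
    two-fold band.
    """

    n_genes: int = 1000
    timepoints: Sequence[str] = ("d0", "d4", "d6")
    genotypes: Sequence[str] = ("WT", "KO")
    n_replicates: int = 2
    n_control_replicates: int = 1  # unlabeled (DMSO) libraries per condition
    library_size_mean: float | None = None  # defaults to 1000 reads per gene
    library_size_dispersion: float = 0.15  # sigma of log-normal library size
    pulse_hours: float = 1.0
    p_err: float = 0.001  # T->C from sequencing / chemistry error
    p_new: float = 0.04  # T->C in 4sU-labeled new RNA after conversion
    u_per_read_mean: float = 30.0  # mean uridine count per read (>= 1)
    hl_range: tuple[float, float] = (0.5, 16.0)
    buffering_fraction: float = 0.3
    buffering_target_corr: float = -0.8
    buffering_sd: float = 0.6  # sd of buffered delta-log2 HL/S draws
    deg_fraction: float = 0.2
    dropout_strength: float = 0.0  # d in [0,1]; labeled-read loss per unit NTR
    # bisulfite block
    n_methylated_sites: int = 200
    nsun2_dependent_fraction: float = 0.5
    methylation_rate_range: tuple[float, float] = (0.2, 0.8)
    background_sites_per_gene: int = 20
    bs_coverage_mean: float = 50.0
    bs_conversion_rate: float = 0.99
    seed: int = 0

    def __post_init__(self):
        for name in ("p_err", "p_new"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {p}")
        if self.p_new <= self.p_err:
            raise ValueError("p_new must exceed p_err")
        if self.hl_range[0] <= 0 or self.hl_range[1] <= self.hl_range[0]:
            raise ValueError("hl_range must be a positive increasing interval")
        if self.buffering_fraction + self.deg_fraction > 1.0 + 1e-12:
            raise ValueError("buffering_fraction + deg_fraction must not exceed 1")
        if not -1.0 <= self.buffering_target_corr <= 0.0:
            raise ValueError("buffering_target_corr must lie in [-1, 0]")
        if not 0.0 <= self.dropout_strength <= 1.0:
            raise ValueError("dropout_strength must lie in [0, 1]")
        if not 0.0 < self.bs_conversion_rate <= 1.0:
            raise ValueError("bs_conversion_rate must lie in (0, 1]")
        if self.u_per_read_mean < 1.0:
            raise ValueError("u_per_read_mean must be >= 1")
        if self.pulse_hours <= 0:
            raise ValueError("pulse_hours must be positive")

    @property
    def resolved_library_size(self) -> float:
        """Mean library size; defaults to a deep 3'-end library (1000 reads/gene)."""
        if self.library_size_mean is not None:
            return float(self.library_size_mean)
        return 1000.0 * self.n_genes

    @property
    def conditions(self) -> list[str]:
        return [f"{g}.{t}" for g in self.genotypes for t in self.timepoints]

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SimulationTruth:
    """Ground truth tables produced by :func:`simulate_truth`.

    ``turnover`` has one row per gene x condition with HL_true (h),
    S_true (units/h) and E_true = S_true*HL_true/ln2; ``gene_class``
    records which structural class each gene belongs to (constant,
    buffered, deg_S, deg_HL); ``annotation`` carries GC fraction and
    3'UTR length; ``methylation`` lists simulated cytosines with one
    true methylation rate column per genotype.
    """

    config: SimulationConfig
    turnover: pd.DataFrame
    gene_class: pd.DataFrame
    annotation: pd.DataFrame
    methylation: pd.DataFrame

    def condition_table(self, condition: str) -> pd.DataFrame:
        sub = self.turnover[self.turnover["condition"] == condition]
        if sub.empty:
            raise KeyError(f"unknown condition {condition!r}")
        return sub.set_index("gene")

    def pi_true(self, condition: str) -> pd.Series:
        """True new-to-total ratio after one pulse: 1 - 2^(-t/HL)."""
        tab = self.condition_table(condition)
        return 1.0 - np.exp(-LN2 * self.config.pulse_hours / tab["HL_true"])


def _gene_names(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"G{i:0{width}d}" for i in range(1, n + 1)])


def simulate_truth(config: SimulationConfig) -> SimulationTruth:
    """Draw per-gene, per-condition turnover parameters with buffering structure.

    The first genotype/timepoint combination is the reference condition.
    A ``buffering_fraction`` of genes receives condition-specific
    (delta log2 HL, delta log2 S) pairs from a bivariate normal with the
    configured negative correlation, nudged so steady-state abundance
    stays within |log2 fc| < 1; a ``deg_fraction`` receives S-driven or
    HL-driven steady-state changes with |log2 fc| > 1; the remainder is
    constant across conditions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_genes
    genes = _gene_names(n)

    hl0 = np.exp(rng.uniform(np.log(config.hl_range[0]), np.log(config.hl_range[1]), n))
    e0 = np.exp(rng.normal(np.log(100.0), 1.0, n))  # heavy-tailed relative abundance
    s0 = e0 * LN2 / hl0

    n_buf = int(round(config.buffering_fraction * n))
    n_deg = int(round(config.deg_fraction * n))
    if n_buf + n_deg > n:
        raise ValueError("gene-class fractions exceed the gene count")
    order = rng.permutation(n)
    buf_idx = order[:n_buf]
    deg_idx = order[n_buf : n_buf + n_deg]
    deg_s_idx = deg_idx[: n_deg // 2]
    deg_hl_idx = deg_idx[n_deg // 2 :]

    gene_class = np.full(n, "constant", dtype=object)
    gene_class[buf_idx] = "buffered"
    gene_class[deg_s_idx] = "deg_S"
    gene_class[deg_hl_idx] = "deg_HL"

    # buffering_target_corr is a Spearman target; for a bivariate normal the
    # matching Pearson correlation is 2 sin(pi * rho_s / 6)
    rho = 2.0 * np.sin(np.pi * config.buffering_target_corr / 6.0)
    sd = config.buffering_sd
    cov = np.array([[sd**2, rho * sd**2], [rho * sd**2, sd**2]])

    baseline = config.conditions[0]
    rows = []
    for cond in config.conditions:
        d_hl = np.zeros(n)
        d_s = np.zeros(n)
        if cond != baseline:
            if n_buf:
                draws = rng.multivariate_normal([0.0, 0.0], cov, size=n_buf)
                lfc_e = draws.sum(axis=1)
                # keep buffered genes steady-state stable: |log2 E fc| < 1
                over = np.abs(lfc_e) >= 1.0
                draws[over, 1] -= lfc_e[over] - np.sign(lfc_e[over]) * 0.95
                d_hl[buf_idx] = draws[:, 0]
                d_s[buf_idx] = draws[:, 1]
            if len(deg_s_idx):
                mag = rng.uniform(1.2, 2.5, len(deg_s_idx))
                d_s[deg_s_idx] = mag * rng.choice([-1.0, 1.0], len(deg_s_idx))
            if len(deg_hl_idx):
                mag = rng.uniform(1.2, 2.5, len(deg_hl_idx))
                d_hl[deg_hl_idx] = mag * rng.choice([-1.0, 1.0], len(deg_hl_idx))
        hl = hl0 * 2.0**d_hl
        s = s0 * 2.0**d_s
        rows.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "condition": cond,
                    "HL_true": hl,
                    "S_true": s,
                    "E_true": s * hl / LN2,
                }
            )
        )
    turnover = pd.concat(rows, ignore_index=True)

    annotation = pd.DataFrame(
        {
            "gene": genes,
            "gc_fraction": np.clip(rng.normal(0.45, 0.07, n), 0.2, 0.8),
            "utr3_length": np.maximum(
                30, np.exp(rng.normal(np.log(800.0), 0.8, n)).astype(int)
            ),
        }
    )

    methylation = _simulate_methylation_truth(config, genes, rng)

    return SimulationTruth(
        config=config,
        turnover=turnover,
        gene_class=pd.DataFrame({"gene": genes, "gene_class": gene_class}),
        annotation=annotation,
        methylation=methylation,
    )


def _simulate_methylation_truth(
    config: SimulationConfig, genes: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Cytosine-level methylation ground truth.

    Each of ``n_methylated_sites`` genes carries one methylated cytosine
    (rate drawn from ``methylation_rate_range``); a matching set of null
    genes carries only unmethylated cytosines.  Every selected gene also
    receives ``background_sites_per_gene`` unmethylated cytosines that
    serve as the gene-specific conversion-rate background.  A fraction of
    methylated sites is Nsun2-dependent: their rate is zero in every
    genotype after the first.
    """
    n_meth = min(config.n_methylated_sites, len(genes) // 2)
    picked = rng.choice(len(genes), size=2 * n_meth, replace=False)
    meth_genes = genes[picked[:n_meth]]
    null_genes = genes[picked[n_meth:]]

    records: list[dict] = []
    pos_counter = 1000
    lo, hi = config.methylation_rate_range
    n_dep = int(round(config.nsun2_dependent_fraction * n_meth))
    dep_flags = np.zeros(n_meth, dtype=bool)
    dep_flags[rng.choice(n_meth, size=n_dep, replace=False)] = True

    def add_site(gene, rate_first, rate_other, is_meth, dep):
        nonlocal pos_counter
        pos_counter += rng.integers(50, 500)
        records.append(
            {
                "chrom": f"chr{1 + (len(records) % 19)}",
                "pos_1based": int(pos_counter),
                "strand": "+" if rng.random() < 0.5 else "-",
                "gene": gene,
                "is_methylated": bool(is_meth),
                "nsun2_dependent": bool(dep),
                "rate_first": float(rate_first),
                "rate_other": float(rate_other),
            }
        )

    for i, gene in enumerate(meth_genes):
        rate = rng.uniform(lo, hi)
        add_site(gene, rate, 0.0 if dep_flags[i] else rate, True, dep_flags[i])
        for _ in range(config.background_sites_per_gene):
            add_site(gene, 0.0, 0.0, False, False)
    for gene in null_genes:
        for _ in range(config.background_sites_per_gene):
            add_site(gene, 0.0, 0.0, False, False)

    meth = pd.DataFrame.from_records(records)
    first = config.genotypes[0]
    for g in config.genotypes:
        meth[f"rate_{g}"] = meth["rate_first"] if g == first else meth["rate_other"]
    return meth.drop(columns=["rate_first", "rate_other"])


def simulate_gene_reads(
    pi: float,
    n_reads: int,
    rng: np.random.Generator | int | None = None,
    u_per_read_mean: float = 30.0,
    p_err: float = 0.001,
    p_new: float = 0.04,
    gene: str = "G",
) -> pd.DataFrame:
    """Conversion histogram of a single gene at a known NTR.

    Each of *n_reads* reads is new with probability *pi*, carries
    n ~ 1 + Poisson(u_per_read_mean - 1) uridines and
    k ~ Binomial(n, p_new or p_err) conversions.  Returns a
    (gene, n, k, count) table; useful for parameter-recovery and
    calibration studies at exactly controlled read depth.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    new = rng.random(n_reads) < pi
    n_u = 1 + rng.poisson(u_per_read_mean - 1.0, n_reads)
    k = rng.binomial(n_u, np.where(new, p_new, p_err))
    return (
        pd.DataFrame({"gene": gene, "n": n_u, "k": k})
        .groupby(["gene", "n", "k"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )


def sample_name(condition: str, replicate: int, labeled: bool) -> str:
    tag = "4sU" if labeled else "ctrl"
    return f"{condition}.{tag}.r{replicate}"


def _sample_rng(config: SimulationConfig, condition: str, replicate: int, labeled: bool):
    token = zlib.crc32(sample_name(condition, replicate, labeled).encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, 7, token]))


def simulate_conversion_reads(
    truth: SimulationTruth,
    config: SimulationConfig,
    condition: str,
    replicate: int = 1,
    labeled: bool = True,
    apply_configured_dropout: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sample one library's conversion histograms and raw gene counts.

    Per gene the read count is Poisson around its share of a log-normal
    library size; each read is "new" with probability
    pi = 1 - exp(-ln2 * t / HL_true) when labeled (0 otherwise), carries
    n ~ 1 + Poisson(u_mean - 1) uridines and k ~ Binomial(n, p_new) or
    Binomial(n, p_err) conversions.  Returns the (gene, n, k, count)
    histogram table and the per-gene read-count vector.  When the config
    sets a nonzero ``dropout_strength`` and the library is labeled, new
    reads are additionally lost via :func:`apply_dropout`.
    """
    tab = truth.condition_table(condition)
    rng = _sample_rng(config, condition, replicate, labeled)

    lib = rng.lognormal(np.log(config.resolved_library_size), config.library_size_dispersion)
    weights = tab["E_true"].to_numpy()
    lam = weights / weights.sum() * lib
    m = rng.poisson(lam)

    pi = truth.pi_true(condition).to_numpy() if labeled else np.zeros(len(tab))
    n_new = rng.binomial(m, pi)
    n_old = m - n_new

    genes = tab.index.to_numpy()
    parts = []
    for counts_per_gene, p_conv in ((n_new, config.p_new), (n_old, config.p_err)):
        total = int(counts_per_gene.sum())
        if total == 0:
            continue
        gene_idx = np.repeat(np.arange(len(genes)), counts_per_gene)
        n_u = 1 + rng.poisson(config.u_per_read_mean - 1.0, total)
        k = rng.binomial(n_u, p_conv)
        parts.append(pd.DataFrame({"gene": genes[gene_idx], "n": n_u, "k": k}))
    if parts:
        reads = pd.concat(parts, ignore_index=True)
        hist = (
            reads.groupby(["gene", "n", "k"], observed=True)
            .size()
            .rename("count")
            .reset_index()
            .sort_values(["gene", "n", "k"], ignore_index=True)
        )
    else:
        hist = pd.DataFrame({"gene": [], "n": [], "k": [], "count": []})

    counts = pd.Series(m, index=genes, name=sample_name(condition, replicate, labeled))
    counts.index.name = "gene"

    if labeled and apply_configured_dropout and config.dropout_strength > 0:
        hist, counts = apply_dropout(
            hist,
            counts,
            truth,
            condition,
            config.dropout_strength,
            rng=rng,
            p_err=config.p_err,
            p_new=config.p_new,
        )
    return hist, counts


def apply_dropout(
    hist: pd.DataFrame,
    counts: pd.Series,
    truth: SimulationTruth,
    condition: str,
    d: float,
    rng: np.random.Generator | int | None = None,
    p_err: float | None = None,
    p_new: float | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Thin labeled (new) reads to emulate 4sU dropout.

    Each new read survives with probability 1 - d, so a gene with true
    NTR pi keeps its reads with overall expected retention 1 - d*pi:
    short-lived (high-NTR) genes lose the most reads and their observed
    NTR is biased downward, which is the bias the dropout correction in
    the kinetics stage removes.  At the histogram level a read of class
    (n, k) is new with posterior probability derived from the binomial
    mixture at the gene's true NTR, so rows are thinned binomially with
    retention 1 - d * P(new | n, k, pi_true).  ``d = 0`` returns the
    input unchanged.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError("dropout strength d must lie in [0, 1]")
    if d == 0.0 or hist.empty:
        return hist.copy(), counts.copy()
    if p_err is None:
        p_err = truth.config.p_err
    if p_new is None:
        p_new = truth.config.p_new
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    pi = truth.pi_true(condition)
    pi_g = pi.reindex(hist["gene"]).to_numpy()
    n = hist["n"].to_numpy()
    k = hist["k"].to_numpy()
    # P(new | n, k) under the generating mixture, in a numerically safe form
    log_new = k * np.log(p_new) + (n - k) * np.log1p(-p_new)
    log_old = k * np.log(p_err) + (n - k) * np.log1p(-p_err)
    with np.errstate(divide="ignore"):
        logit = np.log(pi_g) - np.log1p(-pi_g) + log_new - log_old
    p_is_new = 1.0 / (1.0 + np.exp(-logit))
    p_is_new = np.where(pi_g <= 0.0, 0.0, np.where(pi_g >= 1.0, 1.0, p_is_new))

    retention = 1.0 - d * p_is_new
    kept = rng.binomial(hist["count"].to_numpy(), retention)
    out = hist.assign(count=kept)
    out = out[out["count"] > 0].reset_index(drop=True)
    new_counts = out.groupby("gene", observed=True)["count"].sum()
    counts_out = new_counts.reindex(counts.index, fill_value=0).astype(int)
    counts_out.name = counts.name
    return out, counts_out


def simulate_bisulfite(
    truth: SimulationTruth,
    genotype: str,
    replicate: int = 1,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Sample one replicate's BS-seq site table for a genotype.

    Coverage is Poisson around ``bs_coverage_mean`` (floored at 1); the
    non-converted count is Binomial(coverage, r + (1-r)*(1-c)) where r
    is the site's true methylation rate and c the bisulfite conversion
    efficiency, so unmethylated cytosines appear non-converted only
    through incomplete conversion.
    """
    if config is None:
        config = truth.config
    if genotype not in config.genotypes:
        raise KeyError(f"unknown genotype {genotype!r}")
    token = zlib.crc32(f"bs.{genotype}.r{replicate}".encode())
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11, token]))

    meth = truth.methylation
    rate = meth[f"rate_{genotype}"].to_numpy()
    coverage = np.maximum(1, rng.poisson(config.bs_coverage_mean, len(meth)))
    p_nonconv = rate + (1.0 - rate) * (1.0 - config.bs_conversion_rate)
    non_converted = rng.binomial(coverage, p_nonconv)
    return pd.DataFrame(
        {
            "chrom": meth["chrom"],
            "pos_1based": meth["pos_1based"],
            "strand": meth["strand"],
            "gene": meth["gene"],
            "coverage": coverage,
            "non_converted": non_converted,
        }
    )


@dataclass
class SimulatedDataset:
    """A full simulated study: truth plus per-sample tables."""

    truth: SimulationTruth
    samples: pd.DataFrame  # sample, condition, genotype, timepoint, replicate, labeled
    histograms: dict[str, pd.DataFrame]  # sample -> (gene, n, k, count)
    counts: pd.DataFrame  # genes x samples
    bisulfite: dict[tuple[str, int], pd.DataFrame]  # (genotype, replicate) -> sites


def simulate_dataset(config: SimulationConfig, with_bisulfite: bool = True) -> SimulatedDataset:
    """Simulate every sample of the configured design.

    Per condition: ``n_replicates`` labeled libraries and
    ``n_control_replicates`` unlabeled (no-4sU) control libraries, plus
    BS-seq tables per genotype when requested.
    """
    truth = simulate_truth(config)
    sample_rows = []
    histograms: dict[str, pd.DataFrame] = {}
    count_cols: list[pd.Series] = []
    for g in config.genotypes:
        for t in config.timepoints:
            cond = f"{g}.{t}"
            for labeled, n_rep in ((True, config.n_replicates), (False, config.n_control_replicates)):
                for r in range(1, n_rep + 1):
                    name = sample_name(cond, r, labeled)
                    hist, counts = simulate_conversion_reads(truth, config, cond, r, labeled)
                    histograms[name] = hist
                    count_cols.append(counts)
                    sample_rows.append(
                        {
                            "sample": name,
                            "condition": cond,
                            "genotype": g,
                            "timepoint": t,
                            "replicate": r,
                            "labeled": labeled,
                        }
                    )
    counts = pd.concat(count_cols, axis=1).fillna(0).astype(int)
    bisulfite: dict[tuple[str, int], pd.DataFrame] = {}
    if with_bisulfite:
        for g in config.genotypes:
            for r in range(1, config.n_replicates + 1):
                bisulfite[(g, r)] = simulate_bisulfite(truth, g, r, config)
    return SimulatedDataset(
        truth=truth,
        samples=pd.DataFrame(sample_rows),
        histograms=histograms,
        counts=counts,
        bisulfite=bisulfite,
    )
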