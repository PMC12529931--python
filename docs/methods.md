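# Methods

This note documents the statistical models, the synthetic-data
generator, and the numerical and design choices behind `tucseq`.

## Conversion mixture and NTR estimation

**Model.** After a 4sU pulse of duration *t* and chemical conversion, a
read covering *n* uridine positions shows *k* T→C conversions. Reads
from transcripts synthesized during the pulse ("new") convert at rate
p_new; pre-existing reads at the error rate p_err. Conversions are
assumed independent across positions given the read's class, so a
gene's reads follow the two-component binomial mixture with mixing
weight π, the new-to-total ratio. Reads are reduced to their
sufficient statistic (n, k, count); positional and sequence information
is deliberately dropped.

**Rate estimation.** p_err is the pooled Σk/Σn over unlabeled (DMSO
control) libraries, floored at 1e−6 if no conversions were observed —
estimating it from controls rather than jointly keeps the mixture
identifiable and matches the experimental design, which always includes
a no-4sU control. p_new is fitted by EM over all pooled labeled reads
with p_err fixed and a free global mixing weight; the log-likelihood is
non-decreasing per iteration and iteration stops at a change < 1e−8 or
500 rounds.

**Per-gene posterior.** The mixture likelihood is evaluated in log
space on a uniform grid over [0, 1] (default 1000 points) under a flat
prior; log-sum-exp avoids underflow and grid ties resolve to the
smallest π. The posterior is trapezoid-normalized; a moment-matched
Beta(α, β) summary is stored for downstream uncertainty propagation,
and quantiles interpolate the grid CDF. Genes with fewer than
`min_reads` (default 10) informative reads are flagged `insufficient`
and excluded downstream; the experiment's per-gene floor is a
reporting choice, not a model quantity.

**Accuracy.** At 200 reads/gene with ~30 uridines/read, p_new = 0.04
and p_err = 0.001, the per-read Fisher information of the mixture caps
the achievable mean absolute NTR error at ≈ 0.036 over π ~ U(0.05,
0.9) (Cramér–Rao); the grid MAP, posterior mean and posterior median
all land within a few percent of that bound, and 90% credible intervals
cover the truth at ≈ 89–90%. Accuracy improves with read depth, not
with estimator tweaks.

## Kinetics

Steady-state one-compartment turnover: δ = −ln(1 − π)/t, HL = ln 2/δ,
S = δ·E with E the size-factor-normalized abundance (median-of-ratios
over genes nonzero in every sample). π = 0 carries no decay information
within the pulse and is capped at `hl_max` = 48 h; π = 1 is floored at
`hl_min` = 0.05 h; capped entries are flagged so downstream medians
stay finite while remaining identifiable. Both caps are configurable.
Condition summaries are medians across replicates — robust, and
declared here because distribution plots do not pin down a summary
statistic. Replicate NTR posteriors combine by multiplying flat-prior
Beta posteriors: Beta(Σαᵢ − (R−1), Σβᵢ − (R−1)).

## 4sU dropout correction

Dropout is the preferential loss of 4sU-containing (labeled, i.e. new)
molecules during library preparation. If a fraction *d* of labeled
molecules is lost, a gene with true NTR π keeps 1 − d·π of its reads —
short-lived transcripts lose the most — and the *observed* NTR is
biased down: π_obs = π(1 − d)/(1 − d·π). The generator implements
exactly this mechanism (new reads thinned with probability *d*, applied
to the (n, k) histogram through the posterior probability that a read
class is new).

The correction fits the single per-library parameter *d* by weighted
least squares on the trend of log₂(labeled/unlabeled normalized counts)
against the observed NTR, whose model form is a + log₂(1 − d·π) with a
free normalization intercept; weights are inverse variances of the log
count ratio. Counts are restored as c′ = c/(1 − d·π) and the NTR is
inverted in closed form, π′ = π_obs/(1 − d + d·π_obs), which preserves
the observed old-RNA quantity — the reads the correction restores are
new-RNA reads. A one-parameter mechanistic fit was chosen over a
nonparametric smoother because the NTR inversion is extremely sensitive
to trend noise at small π (a 0.05-log₂ wiggle shifts a π = 0.05 gene by
half its value); with *d* fitted near 0 on dropout-free data the
correction is a near-identity (median |log₂ count change| < 0.005 in
simulation), while at d = 0.5 it reduces the median HL bias from ≈ +80%
to under ±5%. Both counts and NTR are corrected and reported.

## Change classification and ROPE

A gene's half-life (or synthesis rate) is called changed between two
conditions iff |log₂fc| > 1 **and** |ROPE| > 0.45. The ROPE statistic
is signed: with Δ the Monte-Carlo posterior of log₂(HL_B/HL_A)
(NTR Beta posteriors propagated through the half-life transform;
default 10⁵ draws standalone, 2×10⁴ in bulk classification, seeded),
it is P(Δ > w) − P(Δ < −w) with half-width w = 0.25 log₂ units. The
decision threshold 0.45 is the published convention; the region width
w is not published, so it is a configurable parameter reported in
output headers, and this statistic is this package's own concrete
definition, not a reproduction of the original tool's internals. The
synthesis-rate statistic adds the fixed log₂ expression offset to the
degradation-rate ratio; expression uncertainty is not propagated.

Steady-state differential expression is a deliberately simple Wald-type
test: per-gene difference of mean log₂ normalized counts over the
pooled standard error (variance floored at 1e−3) against a Student-t
reference with n_A + n_B − 2 df, BH-adjusted. The t reference (rather
than a normal) keeps the null type-I rate at ≈ 5% with 2–3 replicates
per group. Negative-binomial dispersion shrinkage as in dedicated DE
packages is out of scope; with that caveat the test is calibrated on
the generator's Poisson-like counts. A gene is *steady-state stable*
iff |lfc_E| < 1 and q > 0.05 — the gene set on which buffering is
assessed.

## Buffering and bootstrap

Transcript buffering is quantified as the Spearman correlation between
lfc_HL and lfc_S among stable genes. Note an estimation artifact shared
with any method that derives S = δ·E from the same π̂ as HL: π̂ noise
pushes lfc_HL and lfc_S in opposite directions, so the measured
anticorrelation among stable genes is *steeper* than the true
parameter-level correlation (in simulations with a true Spearman of
−0.8, end-to-end estimates land around −0.85 to −0.9). Truth-level
recovery of the generator's target is exact to sampling error because
the generator calibrates its bivariate-normal Pearson correlation to
the requested Spearman via ρ_P = 2·sin(π·ρ_S/6).

Distribution shifts are tested by bootstrap of median(y) − median(x)
with genes as the resampling unit (the compared distributions are
per-gene HL/S values across genes; a paired mode exists as an option),
20 000 iterations by default, percentile intervals at 95/99/99.9% and
the star labels ns/*/**/*** according to the smallest interval
excluding zero. Percentile intervals are the simplest method consistent
with "CI excludes zero" semantics; null false-exclusion rates measure
≈ 4–6% at the 95% level.

## m⁵C site calling

Sites are filtered (coverage strictly > 20, non-converted ≥ 3, rate
> 0.1) and tested one-sided for enrichment of non-conversion against
the gene-specific conversion background — the gene's summed
converted/non-converted counts over all its assayed cytosines,
*excluding the tested site*; intergenic sites fall back to a
conservative fixed conversion rate of 0.9 scaled to a pseudo-total of
1000. The one-sided choice (enrichment only) is declared: a two-sided
test would also flag unusually well-converted sites, which are not
methylation candidates. P-values come from the hypergeometric survival
function (identical to the one-sided Fisher exact test), BH-adjusted
within each replicate. Consensus sites must pass filters and q < 0.05
in every replicate of a condition (a single-replicate condition reduces
to that replicate's significant sites); methyltransferase-dependent
sites are the consensus set difference WT \ KO at matched conditions.
Duplicate and signal-to-noise filters operate on alignment-level
information absent from site tables and are accepted as pre-applied
upstream. Coordinates are 1-based in TSV; the optional BED export is
0-based half-open.

## Clustering and feature association

Half-life (or expression) profiles are summarized across replicates by
the mean, z-scored per gene (population SD; constant profiles are
dropped with a warning rather than assigned arbitrarily) and k-means
clustered with 25 restarts keeping the minimal within-cluster sum of
squares; k defaults to 8 for half-life profiles and is a configuration
value. Stability classes are compared on GC content and 3′UTR length
with the Wilcoxon rank-sum test — exact null when both groups have
≤ 12 members, otherwise normal approximation with continuity
correction — reporting group medians so the direction of the shift is
explicit.

## Synthetic-data generator

The generator emulates a differentiation time-course in two genotypes:
per-gene baseline half-lives log-uniform on [0.5, 16] h, heavy-tailed
expression weights, and for each non-reference condition three gene
classes — *buffered* (ΔlogHL, ΔlogS from a bivariate normal with
negative correlation, nudged so |log₂ΔE| < 1), *steady-state-changed*
(S-driven or HL-driven, |log₂fc| ∈ [1.2, 2.5]) and *constant*. Reads
are sampled per library: log-normal library size (default mean 1000
reads/gene — a deep 3′-end bulk library; σ = 0.15), Poisson gene
counts proportional to E, per-read uridine counts 1 + Poisson(29) (the
+1 forbids uninformative zero-U reads), binomial conversions, default
p_err = 0.001 and p_new = 0.04 — plausible magnitudes for
OsO₄-converted 1 h labeling; the experiment's real conversion rates are
not published, so these are declared assumptions, and everything is
configurable. BS-seq tables draw coverage Poisson around 50 and
non-conversion Binomial(coverage, r + (1 − r)(1 − c)) with conversion
efficiency c = 0.99; half of the methylated sites are
knockout-dependent.

What the generator does **not** emulate — and hence what passing tests
do not certify on real data: positional conversion biases along reads
(M-bias), UMI/PCR duplication structure, multi-isoform ambiguity,
overdispersed (negative-binomial) counts, batch effects, incomplete or
heterogeneous 4sU uptake, and non-steady-state kinetics during fast
state transitions. Parameter recovery here demonstrates correctness of
the estimators under their assumed model, not robustness to those
violations.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; sample-level streams are
derived from the run seed and stable sample-name hashes, so pipeline
reruns are byte-identical file-for-file. The bundled test suite and the
acceptance script size their simulations to single-CPU desk scale —
300–1000 genes for NTR/HL recovery, 2000 genes for buffering and null
site tables, 500 bootstrap calibration repeats at 2000 iterations —
which keeps the full suite at a few minutes while leaving Monte-Carlo
margins well inside the asserted bands.

## Known limitations

- No multi-isoform read assignment; genes are the atomic unit.
- Expression uncertainty is not propagated into the synthesis-rate
  ROPE statistic (only NTR posteriors are).
- The simplified Wald DE is calibrated for the generator's Poisson-like
  counts; strongly overdispersed real data would need the dedicated DE
  packages it stands in for.
- The dropout model assumes a single per-library loss rate; compound
  or saturating dropout would bend the count-ratio trend away from the
  one-parameter form (the fitted-trend table is exported so this is
  checkable).
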