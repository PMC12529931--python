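# tucseq

Analysis toolkit for metabolic RNA labeling experiments read out by
thiouridine-to-cytidine conversion sequencing (TUC-seq), with a focus on
mRNA turnover dynamics: half-lives, synthesis rates, transcript
buffering, and RNA bisulfite m⁵C site calling.

## The problem

In a TUC-seq experiment, cells are pulse-labeled with 4-thiouridine
(4sU) for a short time *t* (typically 1 h). Chemical conversion turns
incorporated 4sU into apparent T→C mutations, so reads from transcripts
synthesized *during* the pulse carry T→C conversions at an elevated
rate p_new, while pre-existing transcripts convert only at the
background error rate p_err. A read covering *n* uridine positions with
*k* observed conversions therefore follows the two-component binomial
mixture

    P(k | n, π) = (1 − π)·Binom(k; n, p_err) + π·Binom(k; n, p_new)

where π is the gene's **new-to-total ratio (NTR)** — the fraction of
its transcript pool made during the pulse. Under steady-state
one-compartment turnover, π determines the degradation rate and
half-life, and together with normalized abundance E the synthesis rate:

    δ = −ln(1 − π) / t,   HL = ln 2 / δ,   S = δ · E,   E = S·HL / ln 2.

Downstream, the package classifies per-gene turnover changes between
conditions (|log₂fc| > 1 **and** a posterior region-of-practical-
equivalence statistic |ROPE| > 0.45), quantifies **transcript
buffering** (anticorrelated ΔHL/ΔS among genes whose steady-state
abundance did not change), tests distribution-level HL/S shifts by
bootstrap of median differences (20 000 iterations, percentile CIs at
95/99/99.9%), and calls m⁵C candidate sites from RNA bisulfite
sequencing tables (coverage > 20, ≥ 3 non-converted reads, rate > 0.1,
one-sided Fisher test against the gene-specific conversion background,
BH correction, all-replicate consensus at FDR < 0.05).

A ground-truthed synthetic-data generator (`tucseq.simdata`) emulates
3′-end conversion libraries — low conversion rates, library-size
variation, 4sU dropout of short-lived transcripts — and BS-seq site
tables, so every stage is testable without sequencing data.

## Worked example

```python
from tucseq import LabelingParams, NtrMixtureModel, TurnoverModel
from tucseq.buffering import buffering_correlation
from tucseq.simdata import SimulationConfig, simulate_dataset

cfg = SimulationConfig(n_genes=300, seed=7)
ds = simulate_dataset(cfg, with_bisulfite=False)

# global rates from one labeled library + its unlabeled (DMSO) control
res = NtrMixtureModel(ds.histograms["WT.d0.4sU.r1"],
                      control=ds.histograms["WT.d0.ctrl.r1"]).fit()
print(res.summary())
```

```
NTR mixture model (two-component binomial)
  genes:            300 (300 with sufficient reads)
  p_err:            0.000981
  p_new:            0.039742
  median NTR (MAP): 0.2022
  median reads:     408
```

The estimated error and conversion rates recover the generator's truth
(p_err = 0.001, p_new = 0.04); the median NTR of ~0.20 corresponds to a
median half-life of ~3 h after a 1 h pulse.

```python
ntr = {s: NtrMixtureModel(ds.histograms[s], rates=res.rates).fit().table
       for s in ds.samples.loc[ds.samples.labeled, "sample"]}
fit = TurnoverModel(ntr, ds.counts, ds.samples, LabelingParams(t=1.0)).fit()
print(fit.summary())

changes = fit.compare("WT.d0", "WT.d4", seed=0)
r, p, n = buffering_correlation(changes)
print(f"buffering Spearman R = {r:.2f} (p = {p:.2g}, n = {n} stable genes)")
```

```
Steady-state turnover model
  pulse duration:  1.0 h
  genes:           300
  conditions:      KO.d0, KO.d4, KO.d6, WT.d0, WT.d4, WT.d6
  median half-life / synthesis by condition:
             KO.d0: HL =   2.92 h, S =   104.75 /h  (n = 300)
             ...
buffering Spearman R = -0.92 (p = 2.1e-86, n = 211 stable genes)
```

`changes` carries per-gene log₂ fold changes of HL and S, their signed
ROPE statistics, steady-state DE results, a change class
(`HL_up`, `S_down`, `HL_and_S`, …) and a `stable` flag; the strongly
negative Spearman correlation among stable genes is the transcript-
buffering signature built into the simulation
(`buffering_target_corr=-0.8`, sharpened here by shared estimation
noise between HL and S — see `docs/methods.md`).

## Command line

The `tucseq` CLI wraps every stage: `simulate`, `estimate-rates`,
`ntr`, `quantify`, `classify`, `buffering`, `bootstrap`, `m5c-call`,
`m5c-consensus`, `m5c-dependent`, `cluster`, `features`, `validate`,
and `run` (the full pipeline from a YAML config):

```bash
tucseq run --outdir results_demo --seed 1
tucseq validate results_demo/*.tsv
```

All outputs are TSV with provenance comment headers (version, seed,
thresholds); reruns with the same seed are byte-identical.

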