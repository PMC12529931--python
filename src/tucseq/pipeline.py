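"""End-to-end pipeline: simulate -> rates -> NTR -> turnover -> contrasts -> m5C.

A single :class:`PipelineConfig` (optionally loaded from YAML) drives
every stage; all randomness derives from its seed, so a rerun with the
same configuration is byte-identical on disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import buffering as _buffering
from . import diffdyn as _diffdyn
from . import features as _features
from . import m5c as _m5c
from . import mixture as _mixture
from .io import read_tsv, write_tsv
from .kinetics import LabelingParams
from .models import NtrMixtureModel, TurnoverModel
from .simdata import SimulationConfig, simulate_dataset

logger = logging.getLogger("tucseq")

__all__ = ["PipelineConfig", "run_pipeline", "validate_tables"]


@dataclass
class PipelineConfig:
    """Everything one run needs: design, thresholds, seeds, output paths."""

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    contrasts: list[tuple[str, str]] = field(default_factory=list)  # (A, B) pairs
    lfc_threshold: float = _diffdyn.DEFAULT_LFC_THRESHOLD
    rope_threshold: float = _diffdyn.DEFAULT_ROPE_THRESHOLD
    rope_width: float = _diffdyn.DEFAULT_ROPE_WIDTH
    rope_draws: int = 20_000
    grid_size: int = _mixture.DEFAULT_GRID_SIZE
    min_reads: int = _mixture.DEFAULT_MIN_READS
    bootstrap_iterations: int = 20_000
    m5c_fdr: float = 0.05
    cluster_k: int = 8
    dropout_correct: bool = True
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.simulate, dict):
            self.simulate = SimulationConfig(**self.simulate)
        self.contrasts = [tuple(c) for c in self.contrasts]
        conditions = set(self.simulate.conditions)
        for a, b in self.contrasts:
            if a not in conditions or b not in conditions:
                raise ValueError(
                    f"contrast ({a}, {b}) references a condition outside "
                    f"the design {sorted(conditions)}"
                )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    @property
    def thresholds(self) -> _diffdyn.ClassifyThresholds:
        return _diffdyn.ClassifyThresholds(
            lfc=self.lfc_threshold, rope=self.rope_threshold, rope_width=self.rope_width
        )

    def default_contrasts(self) -> list[tuple[str, str]]:
        """Baseline-vs-rest within the first genotype plus KO-vs-WT per timepoint."""
        sim = self.simulate
        g0 = sim.genotypes[0]
        t0 = sim.timepoints[0]
        out = [(f"{g0}.{t0}", f"{g0}.{t}") for t in sim.timepoints[1:]]
        for g in sim.genotypes[1:]:
            out += [(f"{g0}.{t}", f"{g}.{t}") for t in sim.timepoints]
        return out


def run_pipeline(config: PipelineConfig, outdir: str | os.PathLike) -> dict:
    """Run every stage on a simulated dataset and write the artifact bundle.

    Returns a manifest dict (also written as ``manifest.json``) listing
    seeds, thresholds and produced files.  Idempotent: identical config
    gives byte-identical outputs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    contrasts = config.contrasts or config.default_contrasts()
    meta = {"seed": config.seed, "thresholds": f"lfc>{config.lfc_threshold},"
            f"rope>{config.rope_threshold},w={config.rope_width}"}
    files: list[str] = []

    def save(df: pd.DataFrame, name: str, **extra):
        write_tsv(df, out / name, {**meta, **extra})
        files.append(name)

    logger.info("simulating dataset (%d genes)", config.simulate.n_genes)
    ds = simulate_dataset(config.simulate)
    save(ds.truth.turnover, "truth_turnover.tsv")
    save(ds.truth.annotation, "annotation.tsv")
    save(ds.samples, "samples.tsv")
    counts_out = ds.counts.reset_index()
    save(counts_out, "counts.tsv")
    hist_long = pd.concat(
        [h.assign(sample=s) for s, h in ds.histograms.items()], ignore_index=True
    )[["gene", "sample", "n", "k", "count"]]
    save(hist_long, "conversion_histograms.tsv")

    logger.info("estimating global conversion rates")
    control_samples = ds.samples.loc[~ds.samples["labeled"], "sample"]
    labeled_samples = ds.samples.loc[ds.samples["labeled"], "sample"]
    control_hist = pd.concat([ds.histograms[s] for s in control_samples], ignore_index=True)
    labeled_hist = pd.concat([ds.histograms[s] for s in labeled_samples], ignore_index=True)
    p_err = _mixture.estimate_error_rate(control_hist)
    p_new = _mixture.estimate_conversion_rate(labeled_hist, p_err)
    rates = _mixture.GlobalRates(p_err=p_err, p_new=p_new)
    save(pd.DataFrame([{"p_err": p_err, "p_new": p_new}]), "global_rates.tsv")

    logger.info("estimating per-gene NTRs for %d labeled samples", len(labeled_samples))
    ntr_tables: dict[str, pd.DataFrame] = {}
    for s in labeled_samples:
        res = NtrMixtureModel(ds.histograms[s], rates=rates).fit(
            grid_size=config.grid_size, min_reads=config.min_reads
        )
        ntr_tables[s] = res.table
        save(res.table.assign(sample=s), f"ntr.{s}.tsv")

    logger.info("quantifying turnover")
    params = LabelingParams(t=config.simulate.pulse_hours)
    results = TurnoverModel(
        ntr_tables, ds.counts, ds.samples, params, dropout_correct=config.dropout_correct
    ).fit()
    save(results.condition_summary, "turnover.tsv")

    change_tables: dict[str, pd.DataFrame] = {}
    buffer_rows, bootstrap_rows = [], []
    for i, (a, b) in enumerate(contrasts):
        logger.info("contrast %s vs %s", b, a)
        changes = results.compare(
            a, b, thresholds=config.thresholds, n_draws=config.rope_draws,
            seed=config.seed + 1000 + i,
        )
        name = f"{b}_vs_{a}"
        change_tables[name] = changes
        save(changes, f"changes.{name}.tsv")
        r, p, n = _buffering.buffering_correlation(changes)
        buffer_rows.append({"contrast": name, "spearman_R": r, "p": p, "n_stable": n})
        for metric in ("HL_hours", "S_per_h"):
            bres = results.bootstrap_shift(
                a, b, metric=metric, iterations=config.bootstrap_iterations,
                seed=config.seed + 2000 + i,
            )
            bootstrap_rows.append({"contrast": name, "metric": metric, **bres.to_row()})
    save(pd.DataFrame(buffer_rows), "buffering.tsv")
    save(pd.DataFrame(bootstrap_rows), "bootstrap.tsv")

    logger.info("calling m5C sites")
    consensus: dict[str, pd.DataFrame] = {}
    for g in config.simulate.genotypes:
        calls = []
        for (gt, rep), sites in ds.bisulfite.items():
            if gt != g:
                continue
            called = _m5c.call_sites(sites)
            save(called, f"m5c_called.{gt}.r{rep}.tsv", fdr=config.m5c_fdr)
            calls.append(called)
        consensus[g] = _m5c.consensus_sites(calls, fdr=config.m5c_fdr)
        save(consensus[g], f"m5c_consensus.{g}.tsv", fdr=config.m5c_fdr)
    overlap = {}
    if len(config.simulate.genotypes) >= 2:
        g0, g1 = config.simulate.genotypes[:2]
        dep = _m5c.dependent_sites(consensus[g0], consensus[g1])
        save(dep, "m5c_dependent.tsv")
        ko_contrasts = [n for n in change_tables if n.startswith(f"{g1}.")]
        if ko_contrasts:
            overlap = _m5c.overlap_with_dynamics(dep, change_tables[ko_contrasts[0]])
            save(pd.DataFrame([overlap]), "m5c_overlap.tsv")

    logger.info("clustering half-life profiles")
    g0 = config.simulate.genotypes[0]
    conds = [f"{g0}.{t}" for t in config.simulate.timepoints]
    profiles = results.halflife_profiles(conds)
    k = min(config.cluster_k, max(1, len(profiles)))
    cluster = _features.zscore_cluster(profiles, k=k, seed=config.seed)
    save(cluster.assignments.reset_index(), "clusters.tsv", k=k)

    feature_rows = []
    for name, changes in change_tables.items():
        up = changes.loc[changes["class"].isin(["HL_up", "HL_and_S"]), "gene"]
        none = changes.loc[changes["class"] == "none", "gene"]
        if len(up) >= 3 and len(none) >= 3:
            for feat in ("gc_fraction", "utr3_length"):
                row = _features.feature_association(up, none, ds.truth.annotation, feat)
                feature_rows.append({"contrast": name, **row})
    save(pd.DataFrame(feature_rows), "feature_association.tsv")

    manifest = {
        "tucseq_version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "contrasts": [list(c) for c in contrasts],
        "global_rates": {"p_err": p_err, "p_new": p_new},
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["simulate"] = dataclasses.asdict(config.simulate)
    for key, value in list(d["simulate"].items()):
        if isinstance(value, tuple):
            d["simulate"][key] = list(value)
    d["contrasts"] = [list(c) for c in d["contrasts"]]
    return d


# ---------------------------------------------------------------------------
# table validation

_SCHEMAS = {
    "truth_turnover": ["gene", "condition", "HL_true", "S_true", "E_true"],
    "conversion_histogram": ["gene", "n", "k", "count"],
    "counts": ["gene"],
    "annotation": ["gene", "gc_fraction", "utr3_length"],
    "bs_sites": ["chrom", "pos_1based", "strand", "gene", "coverage", "non_converted"],
    "ntr": ["gene", "n_reads", "pi_map", "alpha", "beta"],
    "turnover": ["gene", "condition", "E_norm", "HL_hours", "S_per_h"],
}


def _invariant_errors(kind: str, df: pd.DataFrame) -> list[str]:
    errors = []

    def bad_rows(mask, message):
        if mask.any():
            rows = list(np.flatnonzero(mask.to_numpy())[:5] + 2)  # 1-based + header
            errors.append(f"{message} (rows {rows}{'...' if mask.sum() > 5 else ''})")

    if kind == "bs_sites":
        bad_rows(df["non_converted"] > df["coverage"], "non_converted exceeds coverage")
        bad_rows(df["coverage"] < 0, "negative coverage")
    elif kind == "conversion_histogram":
        bad_rows(df["k"] > df["n"], "k exceeds n")
        bad_rows(df["count"] < 0, "negative read count")
    elif kind == "truth_turnover":
        bad_rows(df["HL_true"] <= 0, "non-positive half-life")
        resid = (df["E_true"] - df["S_true"] * df["HL_true"] / np.log(2)).abs()
        bad_rows(resid > 1e-6 * df["E_true"].abs().clip(lower=1.0), "E != S*HL/ln2")
    elif kind == "ntr":
        ok = df["pi_map"].notna()
        bad_rows(ok & ((df["pi_map"] < 0) | (df["pi_map"] > 1)), "pi_map outside [0,1]")
    return errors


def _detect_kind(columns: list[str]) -> str | None:
    best, best_size = None, 0
    for kind, required in _SCHEMAS.items():
        if set(required).issubset(columns) and len(required) > best_size:
            best, best_size = kind, len(required)
    return best


def validate_tables(paths: list[str | os.PathLike]) -> pd.DataFrame:
    """Schema- and invariant-check a set of pipeline TSVs.

    Returns a per-file report with the detected table kind, row count,
    pass/fail status and any error messages (naming offending columns
    or rows).
    """
    rows = []
    for path in paths:
        entry = {"file": str(path), "kind": None, "n_rows": 0, "status": "pass", "message": ""}
        try:
            df = read_tsv(path)
        except Exception as exc:  # malformed/truncated files reported, not raised
            entry.update(status="fail", message=f"parse error: {exc}")
            rows.append(entry)
            continue
        kind = _detect_kind(list(df.columns))
        entry["n_rows"] = len(df)
        if kind is None:
            entry.update(status="fail", message=f"unrecognized schema: columns {list(df.columns)}")
            rows.append(entry)
            continue
        entry["kind"] = kind
        errors = _invariant_errors(kind, df)
        if errors:
            entry.update(status="fail", message="; ".join(errors))
        rows.append(entry)
    return pd.DataFrame(rows)
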