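import numpy as np
import pandas as pd
import pytest

from tucseq.mixture import (
    ConversionHistogram,
    GlobalRates,
    estimate_conversion_rate,
    estimate_error_rate,
)
from tucseq.models import NtrMixtureModel
from tucseq.simdata import SimulationConfig, simulate_dataset, simulate_truth


@pytest.fixture(scope="session")
def small_config():
    """A compact full design: 2 genotypes x 3 timepoints x 2 replicates."""
    return SimulationConfig(n_genes=120, seed=42, n_methylated_sites=30)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_truth(small_dataset):
    return small_dataset.truth


@pytest.fixture(scope="session")
def default_rates():
    return GlobalRates(p_err=0.001, p_new=0.04)


@pytest.fixture(scope="session")
def estimated_rates(small_dataset):
    ds = small_dataset
    ctrl = pd.concat(
        [ds.histograms[s] for s in ds.samples.loc[~ds.samples["labeled"], "sample"]],
        ignore_index=True,
    )
    lab = pd.concat(
        [ds.histograms[s] for s in ds.samples.loc[ds.samples["labeled"], "sample"]],
        ignore_index=True,
    )
    p_err = estimate_error_rate(ctrl)
    p_new = estimate_conversion_rate(lab, p_err)
    return GlobalRates(p_err=p_err, p_new=p_new)


@pytest.fixture(scope="session")
def ntr_tables(small_dataset, estimated_rates):
    ds = small_dataset
    return {
        s: NtrMixtureModel(ds.histograms[s], rates=estimated_rates).fit().table
        for s in ds.samples.loc[ds.samples["labeled"], "sample"]
    }


def make_histogram(gene="G1", entries=((10, 0, 99), (10, 1, 1))):
    n, k, c = zip(*entries)
    return ConversionHistogram(gene=gene, n=np.array(n), k=np.array(k), count=np.array(c))
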