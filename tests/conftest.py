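"""Shared fixtures: a small simulated study reused across test modules."""

import logging

import numpy as np
import pytest

from reprotalk.simulate import SimConfig, simulate_cells, simulate_secretome
from reprotalk import preprocess as pp
from reprotalk.datasets import GeneSetCollection

logging.getLogger("reprotalk").setLevel(logging.ERROR)

SEED = 11


@pytest.fixture(scope="session")
def sim_small():
    """Raw simulated dataset: 8 days x 2 replicates x 100 cells, defaults."""
    config = SimConfig(seed=SEED, cells_per_day=100)
    adata, truth = simulate_cells(config)
    return config, adata, truth


@pytest.fixture(scope="session")
def panel_small(sim_small):
    config, _, truth = sim_small
    return simulate_secretome(config, truth)


@pytest.fixture(scope="session")
def prep_small(sim_small):
    """QC-filtered, downsampled, normalised copy of the small dataset."""
    _, adata, truth = sim_small
    p = pp.QCParams(min_genes=100, cap_per_day=2500, seed=SEED)
    ds = pp.qc_filter(adata.copy(), p)
    ds = pp.downsample_per_timepoint(ds, p)
    ds = pp.normalize_and_filter_genes(ds, p)
    return ds, truth


@pytest.fixture(scope="session")
def gene_sets(sim_small):
    _, _, truth = sim_small
    coll = GeneSetCollection()
    for name, genes in truth.gene_signatures.items():
        role = "phase" if name.endswith("Phase") else "signature"
        coll.add(name, genes, role=role)
    return coll


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
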