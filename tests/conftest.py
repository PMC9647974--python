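import numpy as np
import pandas as pd
import pytest

from metahic import (
    BinnedGenome, ContactMatrix, GeneNetwork, SimulationConfig, make_bins,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_genome():
    """Two tiny chromosomes at 10-bp bins (c1: 10 bins, c2: 5 bins)."""
    return make_bins({"c1": 100, "c2": 50}, 10)


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded synthetic bundle at the default desk-scale conditions,
    shared across tests that only read from it."""
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture
def gene_table():
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC", "gD"],
            "chrom": ["c1", "c1", "c1", "c2"],
            "tss": [5, 35, 72, 8],
            "tes": [25, 48, 95, 30],
            "strand": ["+", "+", "+", "+"],
        }
    )


def random_symmetric_network(n, seed, prefix="g", genome=None, chroms=None):
    """Distinct-weight symmetric network helper used across test modules."""
    rng = np.random.default_rng(seed)
    w = rng.random((n, n))
    w = (w + w.T) / 2
    return GeneNetwork(
        gene_ids=np.array([f"{prefix}{k:04d}" for k in range(n)], dtype=object),
        weights=w,
        genome=genome,
        gene_chroms=chroms,
    )
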