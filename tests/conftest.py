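import numpy as np
import pytest

from mtdemux import simulate_cells, simulate_haplotypes


@pytest.fixture(scope="session")
def two_donor_noiseless():
    """2 donors x 100 cells, deep noiseless coverage, no doublets."""
    haps = simulate_haplotypes(2, (5, 10), n_shared=0, seed=11)
    return haps, simulate_cells(
        haps, 100, 2000, doublet_fraction=0.0, error_rate=0.0, seed=11
    )


@pytest.fixture(scope="session")
def pooled_eight():
    """8 donors x 100 cells, 8% doublets, 2000 reads/cell, low noise."""
    haps = simulate_haplotypes(8, (5, 30), n_shared=3, seed=5)
    return haps, simulate_cells(
        haps, 100, 2000, doublet_fraction=0.08, error_rate=0.002, seed=5
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
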