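import numpy as np
import pytest

from grnimpact import (
    SimulationConfig,
    normalize,
    sample_ground_truth,
    select_genes,
    simulate_counts,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_tfs=8, n_genes=60, n_cells=150, edges_per_gene=2.0,
                            effect_size=2.0, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return sample_ground_truth(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_truth, small_config):
    return simulate_counts(small_truth, small_config)


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    return normalize(small_dataset)


@pytest.fixture(scope="session")
def small_selection(small_normalized):
    return select_genes(small_normalized, n_top=40, alpha=0.01)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
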