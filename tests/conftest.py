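import dataclasses

import numpy as np
import pytest

from ticscore import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """A scaled-down study: 3 training + 1 validation cohorts, 300 genes."""
    return SimulationConfig(
        seed=11,
        n_training=3,
        n_validation=1,
        n_samples=80,
        n_genes=300,
        n_gene_sets=6,
        set_size=30,
        planted_effects=(-1.0, 1.0, -1.0, 0.0, 0.0, 0.0),
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_study(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
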