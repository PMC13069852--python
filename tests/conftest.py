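import numpy as np
import pytest

from markerauc import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition simulation: 4 types x 200 cells, 40 planted
    markers (10/type, means 10 vs 0.1), 40 DE genes (fold 4), 100
    ubiquitous genes, NB dispersion 1, depth in [0.5, 2]."""
    config = SimulationConfig(seed=7)
    matrix, annotation, truth = simulate_dataset(config)
    return config, matrix, annotation, truth


@pytest.fixture(scope="session")
def small_sim():
    """A light simulation for structural tests."""
    config = SimulationConfig(
        n_types=3, cells_per_type=40, n_marker=6, n_de=6, n_ubiquitous=12, seed=11
    )
    matrix, annotation, truth = simulate_dataset(config)
    return config, matrix, annotation, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
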