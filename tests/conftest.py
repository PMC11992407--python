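import numpy as np
import pytest

from dropstab import SimulationParams, preset_tree, simulate_baseline


@pytest.fixture(scope="session")
def sep3_small():
    """Small well-separated 3-type dataset shared across tests."""
    params = SimulationParams(n_cells=300, n_genes=500,
                              tree=preset_tree("separate3"), seed=11)
    return simulate_baseline(params)


@pytest.fixture(scope="session")
def nested8_small():
    """Small nested 8-state dataset shared across tests."""
    params = SimulationParams(n_cells=320, n_genes=500,
                              tree=preset_tree("nested8"), seed=11)
    return simulate_baseline(params)


@pytest.fixture(scope="session")
def blobs3():
    """Three well-separated Gaussian blobs in 5 dimensions."""
    rng = np.random.default_rng(5)
    centers = rng.normal(0, 20, size=(3, 5))
    X = np.vstack([c + rng.normal(0, 1, size=(60, 5)) for c in centers])
    y = np.repeat([0, 1, 2], 60)
    return X, y
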