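import numpy as np
import pandas as pd
import pytest

from rsfdebias import SimulationParams
from rsfdebias.simulate import make_landscape, run_observation_simulation


@pytest.fixture(scope="session")
def small_params():
    """Simulation parameters scaled down for fast unit tests."""
    return SimulationParams(grid_shape=(60, 60), n_telemetry=300, n_opportunistic=200, seed=7)


@pytest.fixture(scope="session")
def small_landscape(small_params):
    p = small_params
    return make_landscape(p.grid_shape, np.random.default_rng(p.seed),
                          p.forest_proportion, p.viewpoint_proportion,
                          p.gradient_correlation)


@pytest.fixture(scope="session")
def small_simulation(small_landscape, small_params):
    """One simulated replicate: (telemetry, opportunistic, probability grids)."""
    return run_observation_simulation(small_landscape, small_params,
                                      np.random.default_rng(123))
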