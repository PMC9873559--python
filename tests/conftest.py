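import numpy as np
import pytest

from seatea import grids, params, sinkroute


@pytest.fixture(scope="session")
def table():
    return params.load_ranges()


@pytest.fixture(scope="session")
def constants(table):
    return table[0]


@pytest.fixture(scope="session")
def ranges(table):
    return table[1]


@pytest.fixture(scope="session")
def mean_sample(ranges):
    return params.mean_parameter_set(ranges)


@pytest.fixture(scope="session")
def world():
    """Small synthetic world shared by the slower integration tests."""
    grid = grids.generate_ocean_grid(32, 64, 0.3, seed=11)
    env = grids.generate_env_layers(grid, n_ports=6, seed=12)
    yields = grids.generate_yield_ensemble(grid, env, seed=13)
    return grid, env, yields


@pytest.fixture(scope="session")
def assignment(world, mean_sample):
    grid, env, yields = world
    return sinkroute.optimal_sink_assignment(grid, env, yields, mean_sample)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
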