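import numpy as np
import pytest

from seatrade.foodweb import EnvironmentCell, default_foodweb
from seatrade.synthetic_world import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale world: 10 provinces, 4 coastal, small grids, fixed seed."""
    return WorldConfig(
        n_provinces=10,
        n_coastal=4,
        grid_cells_per_region=4,
        total_supply=1300.0,
        total_demand=1000.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def default_world():
    """The full default synthetic world (31 provinces, 11 coastal)."""
    return generate_world(WorldConfig(seed=11))


@pytest.fixture(scope="session")
def web():
    return default_foodweb()


@pytest.fixture
def cell():
    return EnvironmentCell(c_water=1.0, c_sediment=20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
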