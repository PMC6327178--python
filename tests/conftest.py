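import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from snapindex.lattice import UnitCell
from snapindex.simulate import I3C_CELL, I3C_GEOMETRY, SimulationConfig
from snapindex.table import build_reference_table

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def i3c_cell() -> UnitCell:
    return I3C_CELL


@pytest.fixture(scope="session")
def i3c_geom():
    return I3C_GEOMETRY


@pytest.fixture(scope="session")
def i3c_config() -> SimulationConfig:
    """Default I3C study conditions (small n; tests override as needed)."""
    return SimulationConfig(n_patterns=20, seed=11)


@pytest.fixture(scope="session")
def i3c_table(i3c_config):
    """Full-resolution reference table for the I3C cell (built once)."""
    return build_reference_table(i3c_config.cell, i3c_config.d_min)


@pytest.fixture(scope="session")
def i3c_table_coarse(i3c_cell):
    """Small I3C table (d_min = 4.5 Å) for query-oracle tests."""
    return build_reference_table(i3c_cell, 4.5)


@pytest.fixture(scope="session")
def i3c_table_file(i3c_table, tmp_path_factory):
    path = tmp_path_factory.mktemp("table") / "i3c_table.npz"
    i3c_table.save(path)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
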