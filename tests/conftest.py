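import numpy as np
import pytest

from pm25ens import SimulationConfig, assemble_dataset, generate_network, generate_panel


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_stations=30, n_days=80, seed=11)


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate_panel(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_data):
    return assemble_dataset(small_data.panel_pm25, small_data.panel_pm10,
                            small_data.covariates)


@pytest.fixture(scope="session")
def network_coords():
    """Projected coordinates of a full-size 96-station network."""
    stations, _ = generate_network(SimulationConfig(seed=5))
    return np.array([[s.x, s.y] for s in stations])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
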