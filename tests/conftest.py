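import numpy as np
import pytest

from ncdsim import calibration
from ncdsim.engine import DALYParameters, SimulationConfig
from ncdsim.population import PopulationSpec, generate_population
from ncdsim.risk import default_models


@pytest.fixture(scope="session")
def default_spec():
    return PopulationSpec.default()


@pytest.fixture(scope="session")
def pop_small(default_spec):
    """A modest synthetic population shared across tests."""
    return generate_population(default_spec, 800, seed=42)


@pytest.fixture(scope="session")
def daly_params():
    return DALYParameters.default()


@pytest.fixture(scope="session")
def models():
    return default_models()


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=7, population_size=4000)


@pytest.fixture(scope="session")
def calibrated(pop_small, models, sim_config, daly_params):
    """Models calibrated to the shipped baseline burden targets."""
    return calibration.calibrate_all(
        pop_small, models, calibration.default_targets(), sim_config, daly_params
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
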