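import numpy as np
import pytest

from floralnet import (
    SyntheticConfig,
    TriggerSchedule,
    build_default_topology,
    generate_truth,
    reference_parameters,
)
from floralnet.estimation import monomer_data
from floralnet.synth import simulate_wild_type


@pytest.fixture(scope="session")
def topology():
    return build_default_topology()


@pytest.fixture(scope="session")
def params():
    return reference_parameters()


@pytest.fixture(scope="session")
def schedule():
    return TriggerSchedule()


@pytest.fixture(scope="session")
def config():
    return SyntheticConfig(sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def truth_grid(config):
    """Noise-free total-concentration grid from the reference kinetics."""
    return generate_truth(config)


@pytest.fixture(scope="session")
def monomer_grid(truth_grid, topology):
    return monomer_data(truth_grid, topology)


@pytest.fixture(scope="session")
def wild_type(config):
    """Reduced-model wild-type trajectories, all whorls, 0.05-day grid."""
    return simulate_wild_type(config, t_end=5.0,
                              t_eval=np.arange(0.0, 5.0001, 0.05))
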