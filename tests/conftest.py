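import logging

import pytest

from boolomics.personalize import PatientProfile, build_personalized_model
from boolomics.simulate import SimulationConfig
from boolomics.synthetic import toy_ar_network

logging.getLogger("boolomics").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_net():
    return toy_ar_network()


@pytest.fixture(scope="session")
def neutral_model(toy_net):
    """Toy network personalized with an empty omics profile (all defaults)."""
    return build_personalized_model(PatientProfile("neutral", "AA"), toy_net)


@pytest.fixture()
def fast_config():
    """Small grid/ensemble for unit tests that only need qualitative accuracy."""
    return SimulationConfig(t_max=20.0, n_grid=41, n_trajectories=400, seed=11)
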