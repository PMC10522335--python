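import numpy as np
import pytest
from hypothesis import settings

from hyphal_dialogue import ModelParameters, SimulationSettings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def stochastic_settings() -> SimulationSettings:
    """Study conditions at reduced length: enough burn-in to reach the noisy
    attractor, 60 time units of analysis window."""
    return SimulationSettings(total_time=60.0, burn_in=50.0, seed=0)


@pytest.fixture(scope="session")
def det_settings() -> SimulationSettings:
    return SimulationSettings(total_time=20.0, burn_in=0.0, noise_mode="off")


@pytest.fixture(scope="session")
def canonical_state() -> np.ndarray:
    from hyphal_dialogue import CANONICAL_INITIAL_STATE

    return CANONICAL_INITIAL_STATE.copy()
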