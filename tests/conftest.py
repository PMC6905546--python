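import numpy as np
import pytest

from methanergy import (
    M_SMITHII,
    VesselConfig,
    simulate,
)
from methanergy.synthetic import default_initial_state


@pytest.fixture(scope="session")
def vessel():
    return VesselConfig()


@pytest.fixture(scope="session")
def balch_init(vessel):
    """Default emulated Balch-tube start: 1.7 bar 80/20, small inoculum."""
    return default_initial_state(vessel)


@pytest.fixture(scope="session")
def smithii_run(vessel, balch_init):
    """A dense 72-h M. smithii batch trajectory shared across tests."""
    return simulate(M_SMITHII, vessel, balch_init, np.linspace(0.0, 72.0, 2001))
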