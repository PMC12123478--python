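import numpy as np
import pytest

from tidecoex.emergence import emergence_weights
from tidecoex.population_dynamics import DynamicsParams, N_STAGES, N_STRAINS, N_ZONES, PopulationState
from tidecoex.tide_habitat import build_tidal_schedule


@pytest.fixture(scope="session")
def schedule():
    return build_tidal_schedule()


@pytest.fixture()
def default_params():
    return DynamicsParams()


@pytest.fixture()
def fm_timing():
    return emergence_weights(1, 2.0)


@pytest.fixture()
def nm_timing():
    return emergence_weights(11, 2.0)


@pytest.fixture()
def empty_state():
    return PopulationState(larvae=np.zeros((N_STRAINS, N_ZONES, N_STAGES)), day=1)


def make_state(day=1, cells=None):
    """State builder: cells maps (strain, zone0, stage) -> count."""
    larvae = np.zeros((N_STRAINS, N_ZONES, N_STAGES))
    for (s, z, i), v in (cells or {}).items():
        larvae[s, z, i] = v
    return PopulationState(larvae=larvae, day=day)
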