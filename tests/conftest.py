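import numpy as np
import pytest
from hypothesis import settings

import pytagsim as pt

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return pt.ModelParameters()


@pytest.fixture(scope="session")
def index():
    return pt.enumerate_species()


@pytest.fixture(scope="session")
def base_trajectory(params):
    """Base-case 20 ng/mL trace reused across tests (deterministic)."""
    return pt.simulate_timecourse(params, pt.LigandSpec(dose_ng_ml=20.0))


@pytest.fixture(scope="session")
def fig_panel(params):
    """The four-panel (beta, gamma) x dose grid; expensive, computed once."""
    return pt.dose_response_panel(params)


def random_state(rng, index, scale=1e-7):
    """A random nonnegative 16-species state vector."""
    return rng.uniform(0.0, scale, size=len(index))
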