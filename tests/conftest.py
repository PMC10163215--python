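import numpy as np
import pytest

from genosensor.spr import DEFAULT_SCHEDULE, InjectionPhase, KineticParams


@pytest.fixture
def params():
    """Reference mid-range kinetics used across simulation tests."""
    return KineticParams(ka=1e6, kd=1e-3, rmax=100.0)


@pytest.fixture
def schedule():
    return DEFAULT_SCHEDULE


@pytest.fixture
def concentration():
    return 100e-9


@pytest.fixture
def noise_free_sensorgram(params, schedule):
    from genosensor.spr import simulate_sensorgram

    return simulate_sensorgram(schedule, params, noise_sd=0.0, seed=0)


def make_schedule(concentration, t_assoc=300.0, t_dissoc=600.0):
    return (
        InjectionPhase("association", t_assoc, analyte_concentration=concentration),
        InjectionPhase("dissociation", t_dissoc),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
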