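import numpy as np
import pytest

from equivnoise.observer_sim import CohortSpec, ObserverParams, generate_cohort
from equivnoise.psychometric import PsychometricParams


@pytest.fixture
def params():
    """Study-standard Weibull: slope 3.5, guess 0.5, lapse 0.01, 84% target."""
    return PsychometricParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mini_cohort():
    """Small simulated cohort shared across io/stats tests (6 + 6 children)."""
    spec = CohortSpec(group_sizes={"typical": 6, "dyslexic": 6})
    return generate_cohort(spec, seed=777)


@pytest.fixture
def clean_observer():
    """Low-noise, lapse-free observer that passes every screening rule."""
    return {
        "motion": ObserverParams(sigma_int=3.0, n_samp=4, lapse=0.0),
        "orientation": ObserverParams(sigma_int=2.0, n_samp=4, lapse=0.0),
    }
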