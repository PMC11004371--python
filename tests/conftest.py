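import warnings

import pytest
from hypothesis import HealthCheck, settings

from pvloopva import (
    compliance_setting,
    default_config,
    run_phase1,
    run_phase2,
    run_to_steady_state,
    run_vco_experiment,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def normal_steady():
    """Steady-state trajectory of the normal configuration at 80 bpm."""
    return run_to_steady_state(default_config(80.0))


@pytest.fixture(scope="session")
def normal_vco_ts():
    """A full occlusion run at the normal setting, 80 bpm."""
    return run_vco_experiment(compliance_setting("normal"), 80.0)


@pytest.fixture(scope="session")
def phase1_table():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_phase1()


@pytest.fixture(scope="session")
def phase2_table():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_phase2()
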