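import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emgsynergy import SynergyParams, load_config

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> SynergyParams:
    """Shipped default synergy parameter family."""
    return SynergyParams()


@pytest.fixture(scope="session")
def config():
    """Packaged default simulation configuration."""
    return load_config()


@pytest.fixture(scope="session")
def threshold_trial(config):
    """One completed Threshold-mode trial, shared across tests."""
    from emgsynergy import run_trial, synthesize_emg
    from emgsynergy.taskbench import sustained_schedule

    trace = synthesize_emg(
        sustained_schedule(30.0), 30.0, noise_sd=0.02, seed=11
    )
    return run_trial(config, trace, mapping="threshold", seed=11, record_joints=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
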