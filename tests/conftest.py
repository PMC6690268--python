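import numpy as np
import pytest

from wristcal import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic session, shared across tests."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Deterministic-link session: no count noise, no attenuation, no dropout."""
    cfg = SimulationConfig(
        count_log_sd=0.0,
        rho=1.0,
        lambda_mild=1.0,
        lambda_modsev=1.0,
        dropout=0.0,
        seed=5,
    )
    return simulate_cohort(cfg), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(20190805)
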