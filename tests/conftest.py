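import numpy as np
import pytest

from dhfsim import (
    EnvState,
    NoiseSpec,
    ProbeConfig,
    derive_channel_coefficients,
    simulate_true_readings,
)


@pytest.fixture(scope="session")
def default_probe():
    return ProbeConfig()


@pytest.fixture(scope="session")
def default_coeffs(default_probe):
    return derive_channel_coefficients(default_probe)


@pytest.fixture(scope="session")
def default_env():
    return EnvState(cbt=37.0, t_amb=25.0)


@pytest.fixture(scope="session")
def default_truth(default_coeffs, default_env):
    return simulate_true_readings(default_coeffs, default_env)


@pytest.fixture(scope="session")
def default_noise():
    return NoiseSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)
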