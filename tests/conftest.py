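import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wss.simulate import NoiseModel, ProtocolSpec, generate_calibration, generate_sleep_protocol

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def silent_noise():
    return NoiseModel.silent(seed=0)


@pytest.fixture(scope="session")
def default_noise():
    return NoiseModel(seed=11)


@pytest.fixture(scope="session")
def silent_calibration(silent_noise):
    return generate_calibration(silent_noise, rate=50.0, hold=10.0)


@pytest.fixture(scope="session")
def noisy_calibration(default_noise):
    return generate_calibration(default_noise, rate=50.0, hold=10.0)


@pytest.fixture(scope="session")
def default_protocol_recording():
    return generate_sleep_protocol(ProtocolSpec(), NoiseModel(seed=5), rate=50.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
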