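import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from flimredox import AcquisitionConfig, species_preset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def acq() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def km_preset():
    return species_preset("kmarxianus")


@pytest.fixture(scope="session")
def sc_preset():
    return species_preset("scerevisiae")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
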