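import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qdwi.scheme import default_scheme

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260917)
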