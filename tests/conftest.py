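import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ewtwt as ew

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_spec():
    return ew.SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def battery(default_spec):
    """One seeded (clean, noisy, scaled noise) triple at the default 0 dB."""
    return ew.make_noisy_pair(default_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
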