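import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from edsigma import Measurement, ReflectionGroup

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_group(intensities, sigmas=None, hkl=(1, 2, 3), d_star=0.3):
    """One reflection group with given member intensities (helper used widely)."""
    intensities = list(intensities)
    if sigmas is None:
        sigmas = [1.0] * len(intensities)
    members = [
        Measurement(hkl, float(i), float(s), d_star=d_star)
        for i, s in zip(intensities, sigmas)
    ]
    return ReflectionGroup(hkl, members)


@pytest.fixture
def pair_group():
    return make_group([4.0, 6.0])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
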