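import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from srmeeg.epochs import EpochSet

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochs(data, fs=500.0, t0=-300.0, **kw):
    """EpochSet from a raw array with study-default timing."""
    return EpochSet(np.asarray(data, dtype=float), fs, t0, **kw)


@pytest.fixture
def tone_epochs():
    """Single-channel 10 Hz unit tone across the default epoch window."""
    fs, t0 = 500.0, -300.0
    t = (t0 + np.arange(550) * 1000.0 / fs) / 1000.0
    x = np.sin(2 * np.pi * 10.0 * t)
    return make_epochs(x[None, :, None], fs=fs, t0=t0)
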