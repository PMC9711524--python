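import numpy as np
import pytest
from hypothesis import settings

from pulsesync import CommunityTraces

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_traces(values, dt=1.0 / 6.0, **kwargs):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    time_h = np.arange(values.shape[1]) * dt
    return CommunityTraces(values=values, time_h=time_h, **kwargs)


@pytest.fixture
def cosine_traces():
    """Three communities of a pure 2-h cosine sampled at 10 min for 24 h."""
    t = np.arange(0, 24 + 1e-9, 1.0 / 6.0)
    base = np.cos(2 * np.pi * t / 2.0)
    return make_traces(np.vstack([base, base, base]))


@pytest.fixture
def random_traces(rng):
    """Ten seeded random-walk traces, 200 points."""
    vals = np.cumsum(rng.normal(size=(10, 200)), axis=1)
    return make_traces(vals)
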