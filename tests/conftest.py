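import numpy as np
import pytest

from myoflow.synthetic import SimConfig, _band_limited_texture


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def texture(rng):
    """Band-limited random texture, unambiguous for block matching."""
    return _band_limited_texture((96, 96), 3.0, rng)


@pytest.fixture
def short_config():
    """Small, fast simulation: 120 s at 2 Hz, one or two events."""
    return SimConfig(total_duration=120.0, event_rate_per_10min=6.0, seed=7)


@pytest.fixture
def bench_config():
    """Full-length study conditions: 600 s at 2 Hz."""
    return SimConfig(seed=1)
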