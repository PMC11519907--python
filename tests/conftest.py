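import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cytoshell import FrequencyGrid, isochrysis_galbana, seawater_medium

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def medium():
    return seawater_medium()


@pytest.fixture
def cell():
    """Default fitted double-shell cell model."""
    return isochrysis_galbana()


@pytest.fixture
def grid():
    """Measurement band: 250 kHz - 550 MHz, log-spaced."""
    return FrequencyGrid.log_spaced(250e3, 550e6, 60)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
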