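import numpy as np
import pandas as pd
import pytest

from sleepscape.series import SleepWakeSeries, states_from_string
from sleepscape.rhythm import vdp_limit_cycle

NOON = pd.Timestamp("2024-01-01 12:00:00")


@pytest.fixture
def noon():
    return NOON


@pytest.fixture
def make_series():
    """Build a series from a compact 'SSWWM...' string."""

    def _make(text: str, epoch_len: int = 30, start=NOON) -> SleepWakeSeries:
        return SleepWakeSeries(start, epoch_len, states_from_string(text))

    return _make


@pytest.fixture(scope="session")
def waveform():
    """Default van der Pol cycle (mu=1, 24 h, 1-min resolution), shared."""
    return vdp_limit_cycle(mu=1.0, period=24.0, resolution=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
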