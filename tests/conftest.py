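import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from actipain.actigraphy import EpochSeries

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_series(
    counts,
    device_max: float = 1000.0,
    participant_id: str = "P0",
    worn=None,
    start: str = "2015-01-05",
) -> EpochSeries:
    counts = np.asarray(counts, dtype=float)
    if worn is None:
        worn = np.ones(len(counts), dtype=bool)
    return EpochSeries(
        participant_id=participant_id,
        device_id="D0",
        timestamps=pd.date_range(start, periods=len(counts), freq="min"),
        counts=counts,
        worn=np.asarray(worn, dtype=bool),
        device_max=device_max,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20160913)


@pytest.fixture
def flat_week():
    """Seven complete days at a constant 3 % of device max (count 30/1000)."""
    return make_series(np.full(7 * 1440, 30.0))
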