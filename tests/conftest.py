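import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_spec():
    """A 3-pair, 4-day cohort: fast but exercises every stage."""
    from heatwear.synthetic import CohortSpec
    return CohortSpec.default(seed=7, n_pairs=3, n_days=4)


@pytest.fixture(scope="session")
def small_study(small_spec):
    from heatwear.synthetic import simulate_study
    return simulate_study(small_spec)


@pytest.fixture
def hr_series():
    """A plain 1-min heart-rate series of one hour at 60 bpm."""
    from heatwear.core import Device, SensorSeries
    ts = pd.date_range("2023-02-06 08:00:00", periods=60, freq="60s")
    return SensorSeries(Device.HR,
                        pd.DataFrame({"timestamp": ts, "value": np.full(60, 60.0)}),
                        participant_id="P1")


def make_series(device, timestamps, **cols):
    from heatwear.core import SensorSeries
    return SensorSeries(device, pd.DataFrame({"timestamp": pd.to_datetime(timestamps),
                                              **cols}))
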