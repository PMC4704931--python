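import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bbtagree import CycleParams, CycleSeries, generate_cycle

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_series(temps, pid="P1", illness=None, **kw) -> CycleSeries:
    """Shorthand for building a cycle series from a plain temperature list."""
    return CycleSeries(
        participant_id=pid,
        temps=np.asarray(temps, dtype=float),
        start_date=dt.date(2015, 6, 1),
        illness=illness,
        **kw,
    )


@pytest.fixture
def clean_ovulatory():
    """Noise-free 28-day ovulatory cycle: follicular 36.3, shift 0.4 from
    day 15, nadir on day 14, no missing days."""
    params = CycleParams(
        cycle_length=28,
        ovulatory=True,
        luteal_length=14,
        follicular_mean=36.3,
        shift_magnitude=0.4,
        nadir_depth=0.2,
        daily_noise_sd=0.0,
        missing_prob=0.0,
    )
    series, truth = generate_cycle(params, seed=0)
    return series, truth


@pytest.fixture
def clean_flat():
    """Noise-free 28-day anovulatory (flat) cycle."""
    params = CycleParams(
        cycle_length=28,
        ovulatory=False,
        follicular_mean=36.3,
        daily_noise_sd=0.0,
        missing_prob=0.0,
    )
    series, truth = generate_cycle(params, seed=0)
    return series, truth
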