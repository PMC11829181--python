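import datetime as dt

import numpy as np
import pytest

from biphasic.core import ONE_DAY, CycleRecord, TemperatureSeries
from biphasic.simulate import SimConfig, simulate_cohort

D0 = dt.date(2024, 1, 1)


def day(n: int) -> dt.date:
    """Calendar date for 1-based study day n (day 1 = 2024-01-01)."""
    return D0 + dt.timedelta(days=n - 1)


def make_series(values, valid=None, start=D0, user_id="u"):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    dates = [start + dt.timedelta(days=i) for i in range(len(values))]
    return TemperatureSeries(user_id, dates, values, np.asarray(valid, dtype=bool))


@pytest.fixture
def cycle28():
    """A complete 28-day cycle starting on study day 1."""
    return CycleRecord(
        user_id="u", period_start=day(1), period_end=day(5),
        next_period_start=day(29), age_years=30,
    )


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free, gap-free cohort with tightly controlled phase lengths."""
    return simulate_cohort(
        SimConfig(
            n_users=40, cycles_per_user=1, noise_sd=0.0, missing_prob=0.0,
            luteal_clip=(10, 14), irregularity=0.0, seed=11,
        )
    )


@pytest.fixture(scope="session")
def noisy_cohort():
    """Realistic cohort: nightly noise, missing nights, varied rises."""
    return simulate_cohort(SimConfig(n_users=60, cycles_per_user=2, seed=5))
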