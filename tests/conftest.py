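import numpy as np
import pandas as pd
import pytest

from idiodbn.daily_data import DailySeries, weekend_indicator


def make_series(
    n_days: int = 10,
    start: str = "2021-01-04",  # a Monday
    participant_id: str = "p1",
    group: str = "group_a",
    **overrides,
) -> DailySeries:
    """Hand-built valid daily series; pass arrays via keyword to override."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    base = np.arange(n_days, dtype=float)
    values = {
        "B": 1 + (base % 5),
        "R": 1 + ((base + 2) % 5),
        "PV": 10 + 3 * (base % 7),
        "FS": 5.0 + 0.5 * (base % 4),
        "MS": base % 6,
        "T": 15.0 + np.sin(base),
        "W": weekend_indicator(dates),
    }
    values.update({k: np.asarray(v, dtype=float) for k, v in overrides.items()})
    return DailySeries(
        participant_id=participant_id, group=group, dates=dates, values=values
    )


@pytest.fixture
def tiny_series() -> DailySeries:
    return make_series(10)


@pytest.fixture
def series_with_missing() -> DailySeries:
    s = make_series(12)
    for var, days in (("B", [2, 5]), ("R", [3]), ("FS", [0, 7])):
        s.values[var][days] = np.nan
    return s
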