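"""Calendar-date <-> decimal-year helpers (365.25-day years)."""

from __future__ import annotations

import numpy as np
import pandas as pd

_EPOCH = pd.Timestamp("1970-01-01")
_DAYS_PER_YEAR = 365.25


def to_decimal_year(dates) -> np.ndarray:
    """Convert dates (anything pandas parses) to float years since year 0."""
    ts = pd.to_datetime(dates)
    if isinstance(ts, pd.Timestamp):
        return 1970.0 + (ts - _EPOCH).days / _DAYS_PER_YEAR
    delta = (pd.DatetimeIndex(ts) - _EPOCH).days.to_numpy(dtype=float)
    return 1970.0 + delta / _DAYS_PER_YEAR


def from_decimal_year(years):
    """Convert float years to pandas Timestamps (day resolution)."""
    arr = np.asarray(years, dtype=float)
    days = np.round((arr - 1970.0) * _DAYS_PER_YEAR).astype(int)
    if arr.ndim == 0:
        return _EPOCH + pd.Timedelta(days=int(days))
    return _EPOCH + pd.to_timedelta(days, unit="D")
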