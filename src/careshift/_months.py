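"""Small helpers for the monthly calendar axis.

All public APIs represent a calendar month as a :class:`pandas.Period` with
monthly frequency; strings in ``YYYY-MM`` form are accepted everywhere and
validated strictly (``2020-13`` is rejected rather than rolled over).
"""

from __future__ import annotations

import re

import pandas as pd

_MONTH_RE = re.compile(r"^(\d{4})-(0[1-9]|1[0-2])$")

MonthLike = "pd.Period | str"


def parse_month(value) -> pd.Period:
    """Parse a ``YYYY-MM`` string (or pass through a monthly Period)."""
    if isinstance(value, pd.Period):
        if value.freqstr not in ("M", "ME"):
            raise ValueError(f"period {value!r} does not have monthly frequency")
        return value
    if isinstance(value, str):
        m = _MONTH_RE.match(value.strip())
        if not m:
            raise ValueError(f"malformed month {value!r}: expected YYYY-MM with MM in 01..12")
        return pd.Period(year=int(m.group(1)), month=int(m.group(2)), freq="M")
    raise TypeError(f"cannot interpret {value!r} as a calendar month")


def month_range(start, end) -> pd.PeriodIndex:
    """Contiguous monthly axis from ``start`` to ``end`` inclusive."""
    start, end = parse_month(start), parse_month(end)
    if start > end:
        raise ValueError(f"month range start {start} is after end {end}")
    return pd.period_range(start, end, freq="M")


def month_str(month: pd.Period) -> str:
    return f"{month.year:04d}-{month.month:02d}"
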