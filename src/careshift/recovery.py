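"""Recovery classification of monthly deviation trajectories.

A month is "significantly reduced" when its deviation is negative and its
FDR-adjusted p-value is at most the significance threshold.  Recovery is the
first run of at least three consecutive months without a significant
reduction; the recovery month is the first month of that run (reported
1-based from the start of the disruption window, i.e. January 2020 = 1 under
the default window).  Recovery is *sustained* when no significant reduction
occurs at or after the run's first month, otherwise *partial*.  A trailing
clean run shorter than three months at the end of the study does not count.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from careshift._months import month_str
from careshift.deviations import DeviationEstimate

__all__ = ["RecoveryResult", "classify_recovery", "bad_months"]

_MIN_RUN = 3


@dataclass(frozen=True)
class RecoveryResult:
    entity_id: str
    status: str                        # "none" | "partial" | "sustained"
    recovery_month_index: int | None   # 1-based index of the run's first month
    recovery_month: pd.Period | None

    def __post_init__(self):
        if self.status not in ("none", "partial", "sustained"):
            raise ValueError(f"unknown status {self.status!r}")
        if (self.status == "none") != (self.recovery_month_index is None):
            raise ValueError("recovery_month_index present iff status != none")


def bad_months(estimates, alpha: float = 0.05):
    """Significance flags: True where delta < 0 and adjusted p <= alpha."""
    flags = []
    for est in estimates:
        if est.p_adjusted is None:
            raise ValueError(f"estimate for {est.timeframe!r} lacks an adjusted p-value")
        flags.append(est.delta < 0 and est.p_adjusted <= alpha)
    return flags


def classify_recovery(estimates, entity_id: str | None = None,
                      alpha: float = 0.05, months=None) -> RecoveryResult:
    """Classify an ordered, contiguous sequence of monthly deviation estimates.

    ``estimates`` may be DeviationEstimate objects (adjusted p required) or a
    precomputed boolean bad-flag sequence.  ``months`` optionally supplies
    the calendar months for reporting the recovery month.
    """
    if len(estimates) == 0:
        raise ValueError("no monthly estimates supplied")
    if isinstance(estimates[0], DeviationEstimate):
        if entity_id is None:
            entity_id = estimates[0].entity_id
        tfs = [e.timeframe for e in estimates]
        if months is None and all(tfs):
            months = pd.PeriodIndex(tfs, freq="M")
        if months is not None and not (pd.PeriodIndex(months, freq="M").is_monotonic_increasing
                                       and _contiguous(months)):
            raise ValueError("monthly estimates must be ordered and contiguous")
        flags = bad_months(estimates, alpha)
    else:
        flags = [bool(f) for f in estimates]
    entity_id = entity_id or ""

    # first run of >= _MIN_RUN consecutive non-bad months
    run_start, run_len = None, 0
    for i, bad in enumerate(flags):
        if not bad:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len >= _MIN_RUN:
                break
        else:
            run_start, run_len = None, 0
    if run_len < _MIN_RUN:
        return RecoveryResult(entity_id, "none", None, None)

    sustained = not any(flags[run_start:])
    status = "sustained" if sustained else "partial"
    month = None
    if months is not None:
        month = pd.PeriodIndex(months, freq="M")[run_start]
    return RecoveryResult(entity_id, status, run_start + 1, month)


def _contiguous(months) -> bool:
    idx = pd.PeriodIndex(months, freq="M")
    return bool(((idx[1:].astype("int64") - idx[:-1].astype("int64")) == 1).all())


def recovery_table(results) -> pd.DataFrame:
    """Tabulate recovery results (months as YYYY-MM strings)."""
    return pd.DataFrame(
        [(r.entity_id, r.status, r.recovery_month_index,
          month_str(r.recovery_month) if r.recovery_month is not None else "")
         for r in results],
        columns=["entity_id", "status", "recovery_month_index", "recovery_month"])
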