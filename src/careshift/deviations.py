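"""Deviation statistics against the Monte-Carlo counterfactual.

The primary outcome is the relative deviation

    delta = (observed - expected) / expected

of an observed monthly patient count from its counterfactual expectation.
Uncertainty is quantified by referencing the Monte-Carlo counterfactual
distribution: per-draw deviations give percentile confidence intervals, and
two-sided empirical p-values use the add-one rule ``(1 + count) / (S + 1)``
so that no p-value is ever exactly zero.  Deviations over multi-month
timeframes (calendar quarters, the acute "hiatus" window, the post-hiatus
window) average the joint per-draw deviation distribution across the months
of the timeframe.  Families of p-values are adjusted with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from careshift._months import month_range, parse_month

__all__ = [
    "DeviationEstimate",
    "PeriodDefinition",
    "DEFAULT_PERIODS",
    "point_deviation",
    "monthly_inference",
    "period_inference",
    "bh_adjust",
]

_ZERO_FLOOR = 0.5          # draws of 0 are floored here before the ratio transform
_ZERO_FLAG_FRACTION = 1e-3  # flag the estimate when more than this share of draws is 0


@dataclass
class DeviationEstimate:
    """Deviation of observed from expected utilization over one timeframe."""

    entity_id: str
    timeframe_type: str          # "month" | "quarter" | "period"
    timeframe: str               # "2020-04", "2020Q3", "hiatus", ...
    delta: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n_sims: int
    p_adjusted: float | None = None
    flags: tuple = ()


@dataclass(frozen=True)
class PeriodDefinition:
    """A named contiguous month window."""

    name: str
    start: pd.Period
    end: pd.Period

    def __post_init__(self):
        object.__setattr__(self, "start", parse_month(self.start))
        object.__setattr__(self, "end", parse_month(self.end))
        if self.start > self.end:
            raise ValueError(f"period {self.name!r}: start {self.start} after end {self.end}")

    @property
    def months(self) -> pd.PeriodIndex:
        return month_range(self.start, self.end)


DEFAULT_PERIODS = (
    PeriodDefinition("pre_pandemic", "2017-01", "2019-12"),
    PeriodDefinition("pandemic", "2020-01", "2021-12"),
    PeriodDefinition("hiatus", "2020-03", "2020-05"),
    PeriodDefinition("post_hiatus", "2020-06", "2021-12"),
)


def point_deviation(observed: float, expected: float) -> float:
    """Relative deviation ``(observed - expected) / expected``."""
    if expected <= 0:
        raise ValueError(f"expected must be positive; got {expected}")
    if observed < 0:
        raise ValueError(f"observed must be non-negative; got {observed}")
    return (observed - expected) / expected


def _draw_deviations(observed, draws):
    """Per-draw deviations (observed - y_s) / y_s with the zero floor.

    Returns ``(deviations, zero_fraction)``.
    """
    draws = np.asarray(draws, dtype=float)
    zero_fraction = float(np.mean(draws == 0))
    floored = np.maximum(draws, _ZERO_FLOOR)
    return (observed - floored) / floored, zero_fraction


def _percentile_ci(values: np.ndarray, level: float = 0.95):
    alpha = 1.0 - level
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2], method="inverted_cdf")
    return float(lo), float(hi)


def monthly_inference(observed: int, draws, mu: float, entity_id: str = "",
                      month=None, level: float = 0.95) -> DeviationEstimate:
    """Deviation of one month's count against its counterfactual draws.

    The point estimate uses the model mean ``mu`` as "expected"; the CI is
    the percentile interval of the per-draw deviations; the two-sided
    empirical p-value counts draws at or beyond the observation on each side
    with the add-one rule.
    """
    draws = np.asarray(draws)
    if draws.size == 0:
        raise ValueError("empty draws")
    S = draws.size
    delta = point_deviation(observed, mu)
    d_s, zero_fraction = _draw_deviations(observed, draws)
    ci_lo, ci_hi = _percentile_ci(d_s, level)
    p_low = (1 + np.sum(draws <= observed)) / (S + 1)
    p_high = (1 + np.sum(draws >= observed)) / (S + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    flags = ("zero_draws_floored",) if zero_fraction > _ZERO_FLAG_FRACTION else ()
    timeframe = f"{parse_month(month)}" if month is not None else ""
    return DeviationEstimate(entity_id=entity_id, timeframe_type="month",
                             timeframe=timeframe, delta=float(delta),
                             ci_lower=ci_lo, ci_upper=ci_hi, p_value=float(p),
                             n_sims=S, flags=flags)


def period_inference(observed, draws, mu, entity_id: str = "",
                     name: str = "", timeframe_type: str = "period",
                     level: float = 0.95) -> DeviationEstimate:
    """Average deviation over a multi-month timeframe.

    ``observed`` and ``mu`` are per-month vectors and ``draws`` is the
    aligned (n_months, n_sims) matrix.  The point estimate is the mean of
    per-month point deviations; per-draw averages
    ``mean_m (o_m - y_{m,s}) / y_{m,s}`` give the percentile CI, and the
    two-sided empirical p-value asks whether the per-draw average deviation
    distribution straddles zero (add-one rule).
    """
    observed = np.asarray(observed, dtype=float)
    mu = np.asarray(mu, dtype=float)
    draws = np.asarray(draws)
    if observed.ndim != 1 or len(observed) == 0:
        raise ValueError("need at least one month in the period")
    if draws.shape[0] != len(observed) or len(mu) != len(observed):
        raise ValueError("draw matrix misaligned with observed/mu vectors")
    S = draws.shape[1]
    delta = float(np.mean([point_deviation(o, m) for o, m in zip(observed, mu)]))
    d_s, zero_fraction = _draw_deviations(observed[:, None], draws)
    d_bar = d_s.mean(axis=0)
    ci_lo, ci_hi = _percentile_ci(d_bar, level)
    p_neg = (1 + np.sum(d_bar >= 0)) / (S + 1)
    p_pos = (1 + np.sum(d_bar <= 0)) / (S + 1)
    p = min(1.0, 2.0 * min(p_neg, p_pos))
    flags = ("zero_draws_floored",) if zero_fraction > _ZERO_FLAG_FRACTION else ()
    return DeviationEstimate(entity_id=entity_id, timeframe_type=timeframe_type,
                             timeframe=name, delta=delta,
                             ci_lower=ci_lo, ci_upper=ci_hi, p_value=float(p),
                             n_sims=S, flags=flags)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adj_(i) = min_{j >= i} (m * p_(j) / j)`` on the ascending sort, capped
    at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj
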