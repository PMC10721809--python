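"""Synthetic registry-like monthly count panels with known ground truth.

Real care-utilization registries are rarely redistributable, so the package
generates panels that emulate one: monthly patient counts per diagnosis
entity over a multi-year window, with multiplicative seasonality, a
linear-in-year trend on the log scale, Poisson or negative-binomial
dispersion, and a configurable acute disruption ("shock") — a deep dip in
spring 2020 followed by a partial plateau below the pre-disruption baseline.
Every entity carries its generating parameters (:class:`EntityTruth`), so
downstream estimates can be validated against planted truth.

The shock trajectory is a deliberately minimal piecewise form: the paperless
multiplier is 1 before onset, descends linearly to ``1 - A`` at the nadir
month, then relaxes exponentially toward a long-run plateau ``1 - B``.  This
is a stand-in shape, not an estimate of any real epidemic's dynamics; it is
chosen because it reproduces the qualitative dip-rebound-plateau pattern with
the fewest parameters.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from careshift._months import month_range, month_str, parse_month

__all__ = [
    "ShockProfile",
    "EntityTruth",
    "ClusterSpec",
    "SimConfig",
    "generate_panel",
    "severity_shock_depth",
    "severity_plateau_depth",
    "write_panel_csv",
    "write_truth_json",
    "severity_table",
]


# ---------------------------------------------------------------------------
# shock trajectory
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShockProfile:
    """Piecewise multiplicative disruption applied to an entity's mean.

    Parameters
    ----------
    onset : month
        First disrupted month; every earlier month has multiplier exactly 1.
    nadir : month
        Month of deepest disruption, where the multiplier equals ``1 - nadir_drop``.
    nadir_drop : float
        ``A`` in [0, 1): depth of the dip at the nadir.
    plateau_drop : float
        ``B`` in (-1, 1]: long-run multiplier is ``1 - B``; negative values
        model utilization that ends up above baseline.
    recovery_rate : float
        Per-month exponential rate (>= 0) at which the multiplier relaxes
        from the nadir level toward the plateau.
    """

    onset: pd.Period
    nadir: pd.Period
    nadir_drop: float = 0.0
    plateau_drop: float = 0.0
    recovery_rate: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "onset", parse_month(self.onset))
        object.__setattr__(self, "nadir", parse_month(self.nadir))
        if not 0.0 <= self.nadir_drop < 1.0:
            raise ValueError(f"nadir_drop must be in [0, 1); got {self.nadir_drop}")
        if not -1.0 < self.plateau_drop <= 1.0:
            raise ValueError(f"plateau_drop must be in (-1, 1]; got {self.plateau_drop}")
        if self.recovery_rate < 0:
            raise ValueError("recovery_rate must be >= 0")
        if self.onset > self.nadir:
            raise ValueError(f"onset {self.onset} is after nadir {self.nadir}")

    @classmethod
    def none(cls) -> "ShockProfile":
        """A no-op shock (multiplier 1 everywhere)."""
        return cls(onset=pd.Period("2020-03", "M"), nadir=pd.Period("2020-04", "M"),
                   nadir_drop=0.0, plateau_drop=0.0, recovery_rate=1.0)

    def multiplier(self, month) -> float:
        """Shock multiplier for a single calendar month."""
        m = parse_month(month)
        if m < self.onset:
            return 1.0
        t_pre = self.onset - 1  # last undisturbed month anchors the descent
        if m <= self.nadir:
            frac = (m - t_pre).n / (self.nadir - t_pre).n
            return 1.0 - self.nadir_drop * frac
        lag = (m - self.nadir).n
        low, plateau = 1.0 - self.nadir_drop, 1.0 - self.plateau_drop
        return plateau + (low - plateau) * math.exp(-self.recovery_rate * lag)

    def multipliers(self, months: pd.PeriodIndex) -> np.ndarray:
        return np.array([self.multiplier(m) for m in months])


# ---------------------------------------------------------------------------
# per-entity generating truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntityTruth:
    """Generating parameters of one diagnosis entity's count series.

    The monthly mean is ``exp(b0 + trend * year_index + seasonal(m))``
    multiplied by the shock trajectory; counts are drawn Poisson or
    negative-binomial (size ``theta``, variance ``mu + mu^2/theta``) around it.
    ``harmonics`` is a tuple of ``(period, amplitude, phase)`` triples acting
    on the log scale; ``month_effects`` optionally adds one log-scale effect
    per calendar month (January first) instead of, or on top of, harmonics.
    """

    entity_id: str
    category: str
    baseline_log_mean: float
    trend_per_year: float = 0.0
    harmonics: tuple = ()
    month_effects: tuple | None = None
    dispersion_family: str = "poisson"
    negbin_size: float | None = None
    shock: ShockProfile = field(default_factory=ShockProfile.none)
    cluster_id: int = 0
    severity_rank: int | None = None
    vt_flag: bool | None = None

    def __post_init__(self):
        if self.dispersion_family not in ("poisson", "negbin"):
            raise ValueError(f"unknown dispersion family {self.dispersion_family!r}")
        if self.dispersion_family == "negbin":
            if self.negbin_size is None or self.negbin_size <= 0:
                raise ValueError("negbin_size must be a positive real for negbin entities")
        if self.month_effects is not None and len(self.month_effects) != 12:
            raise ValueError("month_effects must have exactly 12 values (January first)")
        if self.severity_rank is not None and not 1 <= self.severity_rank <= 5:
            raise ValueError("severity_rank must be in 1..5")

    def log_linpred(self, months: pd.PeriodIndex, origin=None) -> np.ndarray:
        origin = parse_month(origin) if origin is not None else months[0]
        t = np.array([(m - origin).n for m in months], dtype=float)
        years = np.array([m.year - origin.year for m in months], dtype=float)
        lp = self.baseline_log_mean + self.trend_per_year * years
        for period, amp, phase in self.harmonics:
            lp = lp + amp * np.sin(2 * np.pi * t / period + phase)
        if self.month_effects is not None:
            eff = np.asarray(self.month_effects, dtype=float)
            lp = lp + eff[[m.month - 1 for m in months]]
        return lp

    def baseline_mean(self, months: pd.PeriodIndex, origin=None) -> np.ndarray:
        """Counterfactual (shock-free) monthly mean."""
        return np.exp(self.log_linpred(months, origin))

    def mean_series(self, months: pd.PeriodIndex, origin=None) -> np.ndarray:
        """Actual generating mean: baseline times the shock multiplier."""
        return self.baseline_mean(months, origin) * self.shock.multipliers(months)


# ---------------------------------------------------------------------------
# panel-level configuration
# ---------------------------------------------------------------------------


def severity_shock_depth(rank: int) -> float:
    """Default planted nadir depth ``A`` by severity rank (1 least severe).

    Monotone decreasing in severity: less severe conditions lose more care.
    """
    return 0.9 - 0.1 * rank


def severity_plateau_depth(rank: int) -> float:
    """Default planted plateau depth ``B`` by severity rank."""
    return 0.25 - 0.04 * rank


@dataclass(frozen=True)
class ClusterSpec:
    """Parameter distribution for one planted trajectory cluster.

    Ranges are uniform; the shock profile is the cluster's central trajectory
    with Gaussian jitter of ``shock_jitter_sd`` on both depth parameters.
    """

    cluster_id: int
    weight: float
    shock: ShockProfile
    base_log_mean: tuple = (math.log(250.0), math.log(3000.0))
    trend_per_year: tuple = (-0.05, 0.05)
    amplitude_12: tuple = (0.05, 0.30)
    poisson_fraction: float = 0.6
    # size range keeps relative dispersion registry-like (CV roughly 4-12%)
    negbin_size: tuple = (80.0, 800.0)
    shock_jitter_sd: float = 0.04


def _default_clusters() -> tuple:
    """Three trajectory archetypes: typical dip-plateau, intense sustained
    reduction, and rebound-to-excess."""
    mk = lambda cid, w, A, B, r: ClusterSpec(
        cluster_id=cid, weight=w,
        shock=ShockProfile(onset="2020-03", nadir="2020-04",
                           nadir_drop=A, plateau_drop=B, recovery_rate=r))
    return (
        mk(0, 0.55, 0.67, 0.13, 1.0),
        mk(1, 0.25, 0.75, 0.30, 0.6),
        mk(2, 0.20, 0.50, -0.05, 1.5),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of a synthetic panel.

    With ``severity_mapping=True`` each annotated entity's shock depths are
    overridden by the severity mapping (``A = 0.9 - 0.1*rank``,
    ``B = 0.25 - 0.04*rank`` by default), planting the inverse
    severity-underutilization relation for downstream association tests.
    """

    n_entities: int = 261
    start: str = "2017-01"
    end: str = "2021-12"
    clusters: tuple = field(default_factory=_default_clusters)
    mean_floor: float = 15.0
    n_categories: int = 13
    severity_fraction: float = 1.0
    severity_mapping: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_entities < 1:
            raise ValueError("n_entities must be >= 1")
        if not self.clusters:
            raise ValueError("at least one cluster spec is required")
        if abs(sum(c.weight for c in self.clusters) - 1.0) > 1e-9:
            raise ValueError("cluster weights must sum to 1")

    @property
    def months(self) -> pd.PeriodIndex:
        return month_range(self.start, self.end)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _entity_rng(master_seed: int, entity_id: str) -> np.random.Generator:
    # substream keyed on (seed, id) so output is independent of entity order
    digest = hashlib.sha256(f"{master_seed}:{entity_id}".encode()).digest()
    entropy = [int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _draw_entity_truth(entity_id: str, config: SimConfig,
                       rng: np.random.Generator) -> EntityTruth:
    weights = np.array([c.weight for c in config.clusters])
    cluster = config.clusters[int(rng.choice(len(weights), p=weights))]

    b0 = float(rng.uniform(*cluster.base_log_mean))
    trend = float(rng.uniform(*cluster.trend_per_year))
    amp = float(rng.uniform(*cluster.amplitude_12))
    phase = float(rng.uniform(0, 2 * np.pi))
    family = "poisson" if rng.random() < cluster.poisson_fraction else "negbin"
    theta = float(rng.uniform(*cluster.negbin_size)) if family == "negbin" else None

    rank = int(rng.integers(1, 6)) if rng.random() < config.severity_fraction else None
    vt = bool(rank >= 4) if rank is not None else None

    shock = cluster.shock
    if config.severity_mapping and rank is not None:
        shock = replace(shock,
                        nadir_drop=severity_shock_depth(rank),
                        plateau_drop=severity_plateau_depth(rank))
    if cluster.shock_jitter_sd > 0:
        shock = replace(
            shock,
            nadir_drop=float(np.clip(
                shock.nadir_drop + rng.normal(0, cluster.shock_jitter_sd), 0.0, 0.85)),
            plateau_drop=float(np.clip(
                shock.plateau_drop + rng.normal(0, cluster.shock_jitter_sd), -0.5, 0.6)),
        )

    category = f"cat{int(rng.integers(config.n_categories)):02d}"
    return EntityTruth(
        entity_id=entity_id, category=category,
        baseline_log_mean=b0, trend_per_year=trend,
        harmonics=((12.0, amp, phase),),
        dispersion_family=family, negbin_size=theta,
        shock=shock, cluster_id=cluster.cluster_id,
        severity_rank=rank, vt_flag=vt,
    )


def _sample_counts(mean: np.ndarray, truth: EntityTruth,
                   rng: np.random.Generator) -> np.ndarray:
    if truth.dispersion_family == "poisson":
        return rng.poisson(mean)
    theta = truth.negbin_size
    return rng.negative_binomial(theta, theta / (theta + mean))


def generate_panel(config: SimConfig, seed: int | None = None):
    """Generate a long-format panel and its ground truth.

    Returns ``(panel, truths)`` where ``panel`` is a DataFrame with columns
    ``entity_id, category, month, count`` (one row per entity-month, months
    as ``YYYY-MM`` strings) and ``truths`` lists one :class:`EntityTruth` per
    entity.  Identical ``(config, seed)`` give byte-identical output; each
    entity's draw depends only on the master seed and its id.
    """
    master_seed = config.seed if seed is None else seed
    months = config.months
    origin = months[0]
    width = max(4, len(str(config.n_entities)))
    frames, truths = [], []
    for i in range(1, config.n_entities + 1):
        entity_id = f"E{i:0{width}d}"
        rng = _entity_rng(master_seed, entity_id)
        truth = _draw_entity_truth(entity_id, config, rng)
        mean = truth.mean_series(months, origin)
        if mean.min() < config.mean_floor:
            raise ValueError(
                f"mean floor violated for {entity_id}: min generating mean "
                f"{mean.min():.2f} < floor {config.mean_floor}")
        counts = _sample_counts(mean, truth, rng)
        frames.append(pd.DataFrame({
            "entity_id": entity_id,
            "category": truth.category,
            "month": [month_str(m) for m in months],
            "count": counts.astype(np.int64),
        }))
        truths.append(truth)
    return pd.concat(frames, ignore_index=True), truths


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def _truth_record(t: EntityTruth) -> dict:
    return {
        "category": t.category,
        "baseline_log_mean": t.baseline_log_mean,
        "trend_per_year": t.trend_per_year,
        "harmonics": [list(h) for h in t.harmonics],
        "month_effects": list(t.month_effects) if t.month_effects else None,
        "dispersion_family": t.dispersion_family,
        "negbin_size": t.negbin_size,
        "shock": {
            "onset": month_str(t.shock.onset),
            "nadir": month_str(t.shock.nadir),
            "nadir_drop": t.shock.nadir_drop,
            "plateau_drop": t.shock.plateau_drop,
            "recovery_rate": t.shock.recovery_rate,
        },
        "cluster_id": t.cluster_id,
        "severity_rank": t.severity_rank,
        "vt_flag": t.vt_flag,
    }


def write_truth_json(truths, path) -> None:
    doc = {t.entity_id: _truth_record(t) for t in truths}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def severity_table(truths) -> pd.DataFrame:
    """Severity annotation table (entities lacking a rank are omitted)."""
    rows = [(t.entity_id, t.severity_rank, t.vt_flag)
            for t in truths if t.severity_rank is not None]
    return pd.DataFrame(rows, columns=["entity_id", "severity_rank", "vt_flag"])
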