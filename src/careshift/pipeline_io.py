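"""Panel I/O, inclusion filtering, configuration and end-to-end orchestration.

The pipeline mirrors the framework's four stages: (1) validate the monthly
count panel and apply the utilization-level inclusion rule, (2) fit and
select per-entity counterfactual models on the pre-disruption window and
drop entities whose selected model predicts poorly out of sample
(RMSPE >= 12.5% by default), (3) draw Monte-Carlo counterfactuals and
compute monthly / quarterly / named-period deviations with BH-adjusted
empirical p-values, (4) classify recovery and characterize cross-entity
patterns (clustering, heatmap intensities, severity tests).

Every numeric output is reproducible from ``(panel, config)``: per-entity
simulation seeds are derived by hashing the master seed with the entity id,
so results do not depend on the order of panel rows.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from careshift._months import month_range, month_str, parse_month, _MONTH_RE
from careshift.deviations import (
    DeviationEstimate, PeriodDefinition, bh_adjust, monthly_inference, period_inference,
)
from careshift.models import (
    FitError, FittedCounterfactual, fit_entity, prediction_intervals, simulate_counterfactual,
)
from careshift.patterns import (
    DEFAULT_QUARTERS, heatmap_intensity, hierarchical_cluster, kruskal_wallis,
    quarter_of, quarterly_matrix, rank_sum_test, severity_regression,
)
from careshift.recovery import classify_recovery, recovery_table

logger = logging.getLogger("careshift")

__all__ = [
    "MonthlyPanel",
    "PipelineConfig",
    "PipelineResult",
    "read_panel",
    "read_severity",
    "inclusion_filter",
    "run_pipeline",
    "write_outputs",
    "estimates_to_frame",
]


# ---------------------------------------------------------------------------
# panel container and validation
# ---------------------------------------------------------------------------


@dataclass
class MonthlyPanel:
    """Observed monthly counts for all entities on one contiguous month axis.

    ``counts`` is a wide DataFrame (rows: monthly PeriodIndex, columns:
    entity ids); ``categories`` maps entity id -> category label.
    """

    counts: pd.DataFrame
    categories: dict

    def __post_init__(self):
        idx = self.counts.index
        if not isinstance(idx, pd.PeriodIndex):
            raise TypeError("panel index must be a monthly PeriodIndex")
        gaps = idx[1:].astype("int64") - idx[:-1].astype("int64")
        if len(idx) > 1 and not (gaps == 1).all():
            raise ValueError("month axis must be strictly increasing and contiguous")
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        missing = set(self.counts.columns) - set(self.categories)
        if missing:
            raise ValueError(f"entities lacking a category label: {sorted(missing)}")

    @property
    def entities(self) -> list:
        return list(self.counts.columns)

    @property
    def months(self) -> pd.PeriodIndex:
        return self.counts.index

    def series(self, entity_id: str, start=None, end=None) -> pd.Series:
        s = self.counts[entity_id]
        if start is not None or end is not None:
            s = s.loc[parse_month(start) if start else None:
                      parse_month(end) if end else None]
        return s

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "MonthlyPanel":
        """Build from a long table with entity_id, category, month, count."""
        return _panel_from_long(df.copy())

    def to_long(self) -> pd.DataFrame:
        rows = self.counts.reset_index(names="month").melt(
            id_vars="month", var_name="entity_id", value_name="count")
        rows["category"] = rows["entity_id"].map(self.categories)
        rows["month"] = rows["month"].astype(str)
        return rows[["entity_id", "category", "month", "count"]].sort_values(
            ["entity_id", "month"], ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)


def _panel_from_long(df: pd.DataFrame) -> MonthlyPanel:
    required = ["entity_id", "category", "month", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"panel is missing columns {missing}")
    for i, raw in enumerate(df["month"].astype(str)):
        if not _MONTH_RE.match(raw.strip()):
            raise ValueError(f"row {i}: malformed month {raw!r} (expected YYYY-MM)")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise ValueError(f"row {i}: count {df['count'].iloc[i]!r} is not a "
                         "non-negative integer")
    df["count"] = counts.astype(np.int64)
    df["month"] = pd.PeriodIndex(df["month"].astype(str).str.strip(), freq="M")

    dup = df.duplicated(subset=["entity_id", "month"])
    if dup.any():
        i = int(np.argmax(dup.to_numpy()))
        raise ValueError(f"duplicate entity-month row: "
                         f"({df['entity_id'].iloc[i]}, {df['month'].iloc[i]})")
    cat = df.drop_duplicates("entity_id").set_index("entity_id")["category"].to_dict()
    wide = df.pivot(index="month", columns="entity_id", values="count")
    wide = wide[sorted(wide.columns)]
    if wide.isna().any().any():
        ent = wide.columns[wide.isna().any()][0]
        mth = wide.index[wide[ent].isna()][0]
        raise ValueError(f"missing cell for entity {ent!r} at month {mth}")
    full = pd.period_range(wide.index.min(), wide.index.max(), freq="M")
    if len(full) != len(wide.index):
        gap = sorted(set(full) - set(wide.index))[0]
        raise ValueError(f"gap in month axis at {gap}")
    return MonthlyPanel(counts=wide.astype(np.int64), categories=cat)


def read_panel(path) -> MonthlyPanel:
    """Read and validate a long-format panel CSV
    (header ``entity_id,category,month,count``)."""
    return _panel_from_long(pd.read_csv(path, dtype={"entity_id": str, "category": str,
                                                     "month": str}))


def read_severity(path) -> pd.DataFrame:
    """Severity annotations: entity_id plus severity_rank (1-5) and/or vt_flag."""
    df = pd.read_csv(path, dtype={"entity_id": str})
    if "entity_id" not in df.columns:
        raise ValueError("severity table needs an entity_id column")
    if "severity_rank" in df.columns:
        ranks = df["severity_rank"].dropna()
        if not ranks.isin([1, 2, 3, 4, 5]).all():
            raise ValueError("severity_rank values must be in 1..5")
    return df


# ---------------------------------------------------------------------------
# inclusion rules
# ---------------------------------------------------------------------------


def inclusion_filter(panel: MonthlyPanel, fits: dict | None = None,
                     min_count: int = 10, rmspe_max: float = 0.125):
    """Two-stage inclusion rule.

    Stage 1 drops entities whose count falls to single digits (below
    ``min_count``) in any study month; stage 2 drops entities whose selected
    counterfactual model has out-of-sample RMSPE at or above ``rmspe_max``.
    Returns ``(included_ids, exclusions)`` with a reason per excluded entity.
    """
    included, exclusions = [], {}
    for ent in panel.entities:
        low = panel.counts[ent] < min_count
        if low.any():
            m = panel.months[np.argmax(low.to_numpy())]
            exclusions[ent] = (f"below single-digit threshold: count "
                               f"{int(panel.counts[ent][m])} in {m}")
            continue
        if fits is not None and ent in fits:
            err = fits[ent].rmspe
            if not np.isfinite(err) or err >= rmspe_max:
                exclusions[ent] = f"poor model performance: RMSPE {err:.4f} >= {rmspe_max}"
                continue
        included.append(ent)
    return included, exclusions


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _default_periods() -> tuple:
    # named summary windows inside the prediction window
    return (PeriodDefinition("pandemic", "2020-01", "2021-12"),
            PeriodDefinition("hiatus", "2020-03", "2020-05"),
            PeriodDefinition("post_hiatus", "2020-06", "2021-12"))


@dataclass
class PipelineConfig:
    """Structured run configuration with the study's default windows."""

    train_start: str = "2017-01"
    train_end: str = "2019-12"
    predict_start: str = "2020-01"
    predict_end: str = "2021-12"
    n_sims: int = 10_000
    seed: int = 0
    fdr: float = 0.05
    rmspe_max: float = 0.125
    min_monthly_count: int = 10
    level: float = 0.95
    k_clusters: int = 3
    quarters: tuple = DEFAULT_QUARTERS
    periods: tuple = field(default_factory=_default_periods)
    # draws resample coefficients asymptotic-normally by default: conditional
    # draws alone undercover (~2 points at 95%) once model selection and
    # trend extrapolation are in play; set False for conditional-only draws
    propagate_coef_uncertainty: bool = True

    def __post_init__(self):
        for name in ("train_start", "train_end", "predict_start", "predict_end"):
            parse_month(getattr(self, name))
        if parse_month(self.train_end) >= parse_month(self.predict_start):
            raise ValueError("training window must end before the prediction window")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")

    @property
    def train_months(self) -> pd.PeriodIndex:
        return month_range(self.train_start, self.train_end)

    @property
    def predict_months(self) -> pd.PeriodIndex:
        return month_range(self.predict_start, self.predict_end)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "periods" in doc:
            doc["periods"] = tuple(PeriodDefinition(p["name"], p["start"], p["end"])
                                   for p in doc["periods"])
        if "quarters" in doc:
            doc["quarters"] = tuple(doc["quarters"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["quarters"] = list(self.quarters)
        d["periods"] = [{"name": p.name, "start": month_str(p.start),
                         "end": month_str(p.end)} for p in self.periods]
        return d


def _entity_sim_seed(master_seed: int, entity_id: str) -> int:
    digest = hashlib.sha256(f"sim:{master_seed}:{entity_id}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    config: PipelineConfig
    fits: dict
    exclusions: dict
    deviations: pd.DataFrame
    intervals: pd.DataFrame
    recovery: pd.DataFrame
    cluster: object | None
    heatmap: pd.DataFrame | None
    severity_tests: dict
    report: dict


def estimates_to_frame(estimates) -> pd.DataFrame:
    return pd.DataFrame([{
        "entity_id": e.entity_id, "timeframe_type": e.timeframe_type,
        "timeframe": e.timeframe, "delta": e.delta,
        "ci_lower": e.ci_lower, "ci_upper": e.ci_upper,
        "p_value": e.p_value, "p_adjusted": e.p_adjusted,
        "n_sims": e.n_sims, "flags": ";".join(e.flags),
    } for e in estimates])


def _adjust_family(estimates, fdr: float) -> None:
    if not estimates:
        return
    adj = bh_adjust([e.p_value for e in estimates])
    for e, a in zip(estimates, adj):
        e.p_adjusted = float(a)


def run_pipeline(panel: MonthlyPanel, config: PipelineConfig | None = None,
                 severity: pd.DataFrame | None = None) -> PipelineResult:
    """Execute the full framework on a validated panel.

    Stages: inclusion filtering, per-entity model selection and dispersion
    routing, Monte-Carlo deviation inference with BH adjustment, recovery
    classification, clustering and (when a severity table is supplied)
    severity-association tests.  Fully reproducible from
    ``(panel, config)``.
    """
    config = config or PipelineConfig()
    predict_months = config.predict_months

    # --- stage 1: utilization-level rule, then fitting, then RMSPE rule
    stage1_ok, exclusions = inclusion_filter(panel, fits=None,
                                             min_count=config.min_monthly_count)
    fits: dict[str, FittedCounterfactual] = {}
    for ent in stage1_ok:
        series = panel.series(ent, config.train_start, config.train_end)
        try:
            fits[ent] = fit_entity(series, ent)
        except (FitError, ValueError) as exc:
            exclusions[ent] = f"fit failure: {exc}"
            logger.warning("entity %s dropped: %s", ent, exc)
    fitted_ok = [e for e in stage1_ok if e in fits]
    included, rmspe_excl = [], {}
    for ent in fitted_ok:
        err = fits[ent].rmspe
        if not np.isfinite(err) or err >= config.rmspe_max:
            rmspe_excl[ent] = f"poor model performance: RMSPE {err:.4f} >= {config.rmspe_max}"
        else:
            included.append(ent)
    exclusions.update(rmspe_excl)
    logger.info("included %d of %d entities", len(included), len(panel.entities))

    # --- stages 2-3: Monte-Carlo counterfactuals and deviation inference
    monthly_by_entity: dict[str, list] = {}
    quarterly_est: list[DeviationEstimate] = []
    period_est: dict[str, list] = {p.name: [] for p in config.periods}
    pi_rows = []
    quarter_months = {q: [m for m in predict_months if quarter_of(m) == q]
                      for q in config.quarters}
    active_periods = [p for p in config.periods
                      if p.start >= predict_months[0] and p.end <= predict_months[-1]]

    for ent in included:
        fit = fits[ent]
        draws = simulate_counterfactual(
            fit, predict_months, config.n_sims, _entity_sim_seed(config.seed, ent),
            propagate_coef_uncertainty=config.propagate_coef_uncertainty)
        observed = panel.series(ent, config.predict_start, config.predict_end)
        obs = observed.to_numpy()
        pos = {m: i for i, m in enumerate(predict_months)}

        monthly = [monthly_inference(int(obs[i]), draws.draws[i], draws.mu[i],
                                     entity_id=ent, month=m, level=config.level)
                   for i, m in enumerate(predict_months)]
        monthly_by_entity[ent] = monthly

        for pi in prediction_intervals(draws, config.level):
            pi_rows.append((ent, month_str(pi.month), float(draws.mu[pos[pi.month]]),
                            pi.lower, pi.upper, pi.level))

        for q, q_months in quarter_months.items():
            idx = [pos[m] for m in q_months]
            quarterly_est.append(period_inference(
                obs[idx], draws.draws[idx], draws.mu[idx], entity_id=ent,
                name=q, timeframe_type="quarter", level=config.level))
        for p in active_periods:
            idx = [pos[m] for m in p.months]
            period_est[p.name].append(period_inference(
                obs[idx], draws.draws[idx], draws.mu[idx], entity_id=ent,
                name=p.name, timeframe_type="period", level=config.level))

    # --- FDR families: all monthly; all quarterly; each named period
    all_monthly = [e for ent in included for e in monthly_by_entity[ent]]
    _adjust_family(all_monthly, config.fdr)
    _adjust_family(quarterly_est, config.fdr)
    for name in period_est:
        _adjust_family(period_est[name], config.fdr)

    all_estimates = (all_monthly + quarterly_est
                     + [e for name in period_est for e in period_est[name]])
    deviations = estimates_to_frame(all_estimates)
    intervals = pd.DataFrame(pi_rows, columns=["entity_id", "month", "mu",
                                               "pi_lower", "pi_upper", "level"])

    # --- stage 4a: recovery
    rec_results = [classify_recovery(monthly_by_entity[ent], entity_id=ent,
                                     alpha=config.fdr, months=predict_months)
                   for ent in included]
    recovery = recovery_table(rec_results)

    # --- stage 4b: clustering and heatmap intensities over post-acute quarters
    cluster = None
    heatmap = None
    if len(included) >= 2 and quarterly_est:
        qmat = quarterly_matrix(quarterly_est, config.quarters)
        k = min(config.k_clusters, len(qmat))
        cluster = hierarchical_cluster(qmat, k)
        inten = {}
        for e in quarterly_est:
            inten.setdefault(e.entity_id, {})[e.timeframe] = heatmap_intensity(
                e.delta, e.p_adjusted)
        heatmap = pd.DataFrame.from_dict(inten, orient="index")[list(config.quarters)]
        heatmap = heatmap.loc[sorted(heatmap.index)]

    # --- stage 4c: severity association
    severity_tests = _severity_tests(severity, period_est, monthly_by_entity, included)

    report = _build_report(panel, config, fits, included, exclusions,
                           period_est, rec_results)
    return PipelineResult(config=config, fits=fits, exclusions=exclusions,
                          deviations=deviations, intervals=intervals,
                          recovery=recovery, cluster=cluster, heatmap=heatmap,
                          severity_tests=severity_tests, report=report)


def _severity_tests(severity, period_est, monthly_by_entity, included) -> dict:
    if severity is None or severity.empty:
        logger.info("no severity table supplied; severity tests skipped")
        return {}
    sev = severity.set_index("entity_id")
    out = {}
    for name, ests in period_est.items():
        if name == "pre_pandemic":
            continue
        deltas = {e.entity_id: e.delta for e in ests}
        common = [ent for ent in included if ent in deltas and ent in sev.index]
        if "severity_rank" in sev.columns:
            pairs = [(deltas[ent], sev.loc[ent, "severity_rank"]) for ent in common
                     if not pd.isna(sev.loc[ent, "severity_rank"])]
            if len(pairs) >= 3 and len({r for _, r in pairs}) > 1:
                dev, ranks = zip(*pairs)
                out[f"ols_{name}"] = severity_regression(dev, ranks).to_dict()
                groups = {}
                for d, r in pairs:
                    groups.setdefault(int(r), []).append(d)
                if len(groups) >= 2:
                    out[f"kruskal_wallis_{name}"] = kruskal_wallis(
                        list(groups.values())).to_dict()
        if "vt_flag" in sev.columns:
            vt = [deltas[ent] for ent in common if sev.loc[ent, "vt_flag"] is True
                  or sev.loc[ent, "vt_flag"] == 1]
            nvt = [deltas[ent] for ent in common if sev.loc[ent, "vt_flag"] is False
                   or sev.loc[ent, "vt_flag"] == 0]
            if vt and nvt:
                out[f"rank_sum_vt_{name}"] = rank_sum_test(vt, nvt).to_dict()
    return out


def _build_report(panel, config, fits, included, exclusions, period_est,
                  rec_results) -> dict:
    from careshift import __version__
    period_summaries = {}
    for name, ests in period_est.items():
        if ests:
            deltas = np.array([e.delta for e in ests])
            period_summaries[name] = {"mean_delta": float(deltas.mean()),
                                      "sd_delta": float(deltas.std(ddof=1)) if len(deltas) > 1 else 0.0,
                                      "n": len(deltas)}
    tallies: dict = {"by_status": {}, "by_category": {}}
    for r in rec_results:
        tallies["by_status"][r.status] = tallies["by_status"].get(r.status, 0) + 1
        cat = panel.categories.get(r.entity_id, "")
        tallies["by_category"].setdefault(cat, {"recovered": 0, "total": 0})
        tallies["by_category"][cat]["total"] += 1
        if r.status != "none":
            tallies["by_category"][cat]["recovered"] += 1
    model_summary = {ent: {"spec": str(fits[ent].spec), "family": fits[ent].family,
                           "family_param": fits[ent].family_param,
                           "rmspe": fits[ent].rmspe}
                     for ent in sorted(fits)}
    assert len(included) + len(exclusions) == len(panel.entities)
    return {
        "config": config.to_dict(),
        "version": __version__,
        "n_entities": len(panel.entities),
        "n_included": len(included),
        "exclusions": dict(sorted(exclusions.items())),
        "models": model_summary,
        "period_summaries": period_summaries,
        "recovery_tallies": tallies,
    }


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write the full artifact set (CSV/JSON, plus a Newick dendrogram)."""
    import pathlib
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.deviations.to_csv(outdir / "deviations.csv", index=False)
    result.intervals.to_csv(outdir / "intervals.csv", index=False)
    result.recovery.to_csv(outdir / "recovery.csv", index=False)
    if result.cluster is not None:
        result.cluster.labels.rename_axis("entity_id").reset_index().to_csv(
            outdir / "clusters.csv", index=False)
        pd.DataFrame(result.cluster.linkage,
                     columns=["child_a", "child_b", "height", "n_leaves"]).to_csv(
            outdir / "linkage.csv", index=False)
        (outdir / "dendrogram.nwk").write_text(result.cluster.newick() + "\n")
    if result.heatmap is not None:
        result.heatmap.rename_axis("entity_id").to_csv(outdir / "heatmap_matrix.csv")
    with open(outdir / "severity_tests.json", "w") as fh:
        json.dump(result.severity_tests, fh, indent=1)
    with open(outdir / "fits.json", "w") as fh:
        json.dump({ent: f.to_dict() for ent, f in sorted(result.fits.items())}, fh)
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=1, default=str)
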