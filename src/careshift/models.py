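"""Counterfactual count models: candidate enumeration, blocked CV selection,
dispersion routing, and Monte-Carlo prediction.

For each diagnosis entity a log-link count regression is chosen from a
prespecified ladder of seasonal-trend structures by leave-one-year-out
blocked cross-validation on the pre-disruption window.  The selected model's
residuals are then assessed for overdispersion and the entity is routed to a
Poisson, over-dispersed Poisson (variance ``phi * mu``, simulated by a
moment-matched negative binomial) or negative-binomial (variance
``mu + mu^2/theta``) simulation family.  Monte-Carlo draws from the routed
family over the disruption window define the counterfactual distribution
from which prediction intervals, deviations and empirical p-values are
computed downstream.

Generalized-linear-model fitting is delegated to statsmodels (Poisson family,
log link, IRLS); everything around it — candidate ladder, blocked folds,
mean-variance routing, draw machinery — is implemented here.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from careshift._months import month_range, month_str, parse_month

__all__ = [
    "CandidateModelSpec",
    "FittedCounterfactual",
    "CounterfactualDraws",
    "PredictionInterval",
    "FitError",
    "enumerate_candidates",
    "build_design_matrix",
    "fit_count_glm",
    "blocked_cv_select",
    "assess_dispersion",
    "fit_entity",
    "simulate_counterfactual",
    "prediction_intervals",
    "rmspe",
]


class FitError(RuntimeError):
    """A candidate model failed to fit (rank deficiency or non-convergence)."""


# ---------------------------------------------------------------------------
# candidate specifications
# ---------------------------------------------------------------------------

# seasonal structure -> (harmonic periods, uses month fixed effects, dof)
_SEASONAL_BLOCKS = {
    "none": ((), False, 0),
    "harmonics12": ((12,), False, 2),
    "harmonics12_6": ((12, 6), False, 4),
    "harmonics12_6_3": ((12, 6, 3), False, 6),
    "month_effects": ((), True, 11),
}
_BLOCK_ORDER = ["none", "harmonics12", "harmonics12_6", "harmonics12_6_3", "month_effects"]


@dataclass(frozen=True)
class CandidateModelSpec:
    """One seasonal-trend structure in the candidate ladder."""

    seasonal_block: str
    include_trend: bool
    id: int

    def __post_init__(self):
        if self.seasonal_block not in _SEASONAL_BLOCKS:
            raise ValueError(f"unknown seasonal block {self.seasonal_block!r}")

    @property
    def harmonic_periods(self) -> tuple:
        return _SEASONAL_BLOCKS[self.seasonal_block][0]

    @property
    def uses_month_effects(self) -> bool:
        return _SEASONAL_BLOCKS[self.seasonal_block][1]

    @property
    def n_params(self) -> int:
        return 1 + _SEASONAL_BLOCKS[self.seasonal_block][2] + int(self.include_trend)

    @property
    def has_12m_seasonality(self) -> bool:
        """Whether the spec can represent annual seasonality."""
        return self.uses_month_effects or 12 in self.harmonic_periods

    def __str__(self):
        return f"{self.seasonal_block}{'+trend' if self.include_trend else ''}"


def enumerate_candidates(seasonal_blocks=None, trends=(False, True)):
    """The candidate ladder: seasonal structures crossed with the trend term.

    Defaults to the full 5 x 2 crossing (10 specs).  Specs are ordered by
    parameter count, ids are assigned in that order and are stable for a
    given settings choice.
    """
    blocks = list(seasonal_blocks) if seasonal_blocks is not None else list(_BLOCK_ORDER)
    for b in blocks:
        if b not in _SEASONAL_BLOCKS:
            raise ValueError(f"unknown seasonal block {b!r}")
    raw = [(b, t) for b in blocks for t in trends]
    raw.sort(key=lambda bt: (1 + _SEASONAL_BLOCKS[bt[0]][2] + int(bt[1]),
                             _BLOCK_ORDER.index(bt[0]), bt[1]))
    return [CandidateModelSpec(seasonal_block=b, include_trend=t, id=i)
            for i, (b, t) in enumerate(raw)]


def build_design_matrix(spec: CandidateModelSpec, months: pd.PeriodIndex,
                        origin=None) -> np.ndarray:
    """Design matrix for ``months``.

    ``origin`` is the first month of the *training* window; month index
    ``t`` and the year index are 0-based from it so that prediction months
    extrapolate the same basis.  Month fixed effects use January as the
    reference level (11 indicator columns, February..December).
    """
    if len(months) == 0:
        raise ValueError("empty month range")
    origin = parse_month(origin) if origin is not None else months[0]
    t = np.array([(m - origin).n for m in months], dtype=float)
    cols = [np.ones(len(months))]
    for period in spec.harmonic_periods:
        cols.append(np.sin(2 * np.pi * t / period))
        cols.append(np.cos(2 * np.pi * t / period))
    if spec.uses_month_effects:
        month_no = np.array([m.month for m in months])
        for mm in range(2, 13):
            cols.append((month_no == mm).astype(float))
    if spec.include_trend:
        cols.append(np.array([m.year - origin.year for m in months], dtype=float))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_count_glm(design: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Poisson log-link ML coefficients (IRLS via statsmodels).

    Raises :class:`FitError` on rank deficiency or non-convergence; callers
    treat that as "candidate dropped", not as a fatal error.
    """
    design = np.asarray(design, dtype=float)
    counts = np.asarray(counts)
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FitError("design matrix is rank deficient")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(counts.astype(float), design,
                         family=sm.families.Poisson()).fit(maxiter=100, tol=1e-8)
    except Exception as exc:  # pragma: no cover - statsmodels failure modes vary
        raise FitError(f"GLM fit failed: {exc}") from exc
    if not getattr(res, "converged", True) or not np.all(np.isfinite(res.params)):
        raise FitError("IRLS did not converge")
    return np.asarray(res.params)


def blocked_cv_select(counts: pd.Series, candidates=None):
    """Leave-one-year-out blocked cross-validation over the candidate ladder.

    ``counts`` is indexed by contiguous monthly periods spanning >= 2
    complete-ish calendar years (folds are calendar years).  For each
    candidate, each year is held out in turn, the model is refit on the
    remaining years and the held-out year is scored by mean squared error of
    the predicted means; the candidate score is the average fold MSE.  The
    winner is the lowest score, ties broken by fewest parameters then lowest
    id.  Candidates that fail to fit in any fold are excluded; if every
    candidate fails, an intercept+trend fallback is returned.

    Returns ``(selected_spec, cv_mse, holdout_pred)`` where ``cv_mse`` maps
    candidate id -> score (NaN for failed candidates) and ``holdout_pred`` is
    the selected model's out-of-sample predicted mean for every training
    month (the concatenated holdout predictions).
    """
    months = counts.index
    if not isinstance(months, pd.PeriodIndex):
        raise TypeError("counts must be indexed by a monthly PeriodIndex")
    years = sorted({m.year for m in months})
    if len(years) < 2:
        raise ValueError("blocked CV requires at least 2 calendar years of training data")
    if candidates is None:
        candidates = enumerate_candidates()

    origin = months[0]
    y = counts.to_numpy(dtype=float)
    year_of = np.array([m.year for m in months])
    designs = {spec.id: build_design_matrix(spec, months, origin) for spec in candidates}

    cv_mse: dict[int, float] = {}
    holdouts: dict[int, np.ndarray] = {}
    for spec in candidates:
        X = designs[spec.id]
        fold_mse, pred_all, failed = [], np.full(len(y), np.nan), False
        for year in years:
            hold = year_of == year
            try:
                beta = fit_count_glm(X[~hold], y[~hold])
            except FitError:
                failed = True
                break
            mu = np.exp(X[hold] @ beta)
            pred_all[hold] = mu
            fold_mse.append(float(np.mean((y[hold] - mu) ** 2)))
        if failed:
            cv_mse[spec.id] = float("nan")
        else:
            cv_mse[spec.id] = float(np.mean(fold_mse))
            holdouts[spec.id] = pred_all

    viable = [s for s in candidates if not math.isnan(cv_mse[s.id])]
    if not viable:
        fallback = CandidateModelSpec("none", True, id=-1)
        return fallback, cv_mse, np.full(len(y), np.nan)
    # scores within numerical noise of the minimum count as ties, which are
    # broken by fewest parameters then lowest id
    best = min(cv_mse[s.id] for s in viable)
    tol = 1e-9 * (1.0 + abs(best))
    tied = [s for s in viable if cv_mse[s.id] <= best + tol]
    winner = min(tied, key=lambda s: (s.n_params, s.id))
    return winner, cv_mse, holdouts[winner.id]


def rmspe(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root-mean-squared percentage error, ``sqrt(mean(((o-p)/o)^2))``."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must align")
    if np.any(observed == 0):
        raise ValueError("RMSPE undefined: observed count of 0")
    if np.any(np.isnan(predicted)):
        return float("inf")
    return float(np.sqrt(np.mean(((observed - predicted) / observed) ** 2)))


def assess_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int):
    """Route an entity to its simulation family from the mean-variance shape.

    Pearson dispersion ``phi_hat = sum((y-mu)^2/mu) / (n - p)``; at most 1.2
    the Poisson family is kept.  Above that, the squared-residual excess
    ``(y-mu)^2 - mu`` is regressed (least squares through the origin) on
    ``mu`` (over-dispersed Poisson, variance ``phi*mu``) and on ``mu^2``
    (negative binomial, variance ``mu + mu^2/theta``); the form with the
    smaller residual sum of squares wins.

    Returns ``(family, family_param, phi_hat)`` with ``family_param`` None
    for Poisson, ``phi`` for ODP and ``theta`` for negbin.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    n, p = len(y), n_params
    if n <= p:
        raise ValueError(f"cannot assess dispersion with n={n} <= p={p}")
    phi_hat = float(np.sum((y - mu) ** 2 / mu) / (n - p))
    if phi_hat <= 1.2:
        return "poisson", None, phi_hat
    # squared residuals shrink by ~(n-p)/n after fitting p parameters;
    # rescale so the mean-variance regression is not biased toward
    # under-dispersion in short series
    z = (y - mu) ** 2 * (n / (n - p)) - mu
    a = float(np.sum(z * mu) / np.sum(mu ** 2))        # ODP: z ~ (phi-1)*mu
    b = float(np.sum(z * mu ** 2) / np.sum(mu ** 4))   # NB:  z ~ mu^2/theta
    rss_odp = float(np.sum((z - a * mu) ** 2))
    rss_nb = float(np.sum((z - b * mu ** 2) ** 2))
    if rss_odp <= rss_nb:
        return "overdispersed_poisson", max(1.0 + a, 1.0 + 1e-6), phi_hat
    theta = 1.0 / b if b > 0 else 1e6
    return "negbin", max(theta, 1e-3), phi_hat


# ---------------------------------------------------------------------------
# fitted counterfactual
# ---------------------------------------------------------------------------


@dataclass
class FittedCounterfactual:
    """Selected and dispersion-routed counterfactual model for one entity."""

    entity_id: str
    spec: CandidateModelSpec
    coef: np.ndarray
    coef_cov: np.ndarray | None
    family: str
    family_param: float | None
    phi_hat: float
    cv_mse: dict
    rmspe: float
    origin: pd.Period  # first training month; anchors all design matrices

    def predict_mean(self, months: pd.PeriodIndex) -> np.ndarray:
        X = build_design_matrix(self.spec, months, self.origin)
        return np.exp(X @ self.coef)

    def to_dict(self) -> dict:
        return {
            "entity_id": self.entity_id,
            "spec": {"seasonal_block": self.spec.seasonal_block,
                     "include_trend": self.spec.include_trend, "id": self.spec.id},
            "coef": [float(c) for c in self.coef],
            "coef_cov": None if self.coef_cov is None
                        else [[float(v) for v in row] for row in self.coef_cov],
            "family": self.family,
            "family_param": self.family_param,
            "phi_hat": self.phi_hat,
            "cv_mse": {str(k): v for k, v in self.cv_mse.items()},
            "rmspe": self.rmspe,
            "origin": month_str(self.origin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedCounterfactual":
        return cls(
            entity_id=d["entity_id"],
            spec=CandidateModelSpec(**d["spec"]),
            coef=np.asarray(d["coef"], dtype=float),
            coef_cov=None if d.get("coef_cov") is None
                     else np.asarray(d["coef_cov"], dtype=float),
            family=d["family"], family_param=d["family_param"],
            phi_hat=d["phi_hat"],
            cv_mse={int(k): v for k, v in d["cv_mse"].items()},
            rmspe=d["rmspe"], origin=parse_month(d["origin"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def fit_entity(counts: pd.Series, entity_id: str = "", candidates=None) -> FittedCounterfactual:
    """Full per-entity fitting pipeline on the pre-disruption window.

    Blocked-CV model selection, final refit on the whole training window,
    dispersion routing, and out-of-sample RMSPE of the selected model on the
    concatenated CV holdout predictions.
    """
    spec, cv_mse, holdout_pred = blocked_cv_select(counts, candidates)
    months = counts.index
    X = build_design_matrix(spec, months, months[0])
    y = counts.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError(f"selected design is rank deficient for {entity_id}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100, tol=1e-8)
    if not getattr(res, "converged", True) or not np.all(np.isfinite(res.params)):
        raise FitError(f"final fit did not converge for {entity_id}")
    coef = np.asarray(res.params)
    mu = np.exp(X @ coef)
    family, family_param, phi_hat = assess_dispersion(y, mu, spec.n_params)
    err = rmspe(y, holdout_pred) if np.all(y > 0) else float("inf")
    return FittedCounterfactual(
        entity_id=entity_id, spec=spec, coef=coef, coef_cov=np.asarray(res.cov_params()),
        family=family, family_param=family_param, phi_hat=phi_hat,
        cv_mse=cv_mse, rmspe=err, origin=months[0],
    )


# ---------------------------------------------------------------------------
# Monte-Carlo counterfactual draws
# ---------------------------------------------------------------------------


@dataclass
class CounterfactualDraws:
    """Monte-Carlo counterfactual count distribution over a month window."""

    entity_id: str
    months: pd.PeriodIndex
    mu: np.ndarray          # expected mean per month
    draws: np.ndarray       # (n_months, n_sims) integer counts

    @property
    def n_sims(self) -> int:
        return self.draws.shape[1]


def simulate_counterfactual(fit: FittedCounterfactual, months, n_sims: int,
                            seed: int, propagate_coef_uncertainty: bool = False
                            ) -> CounterfactualDraws:
    """Simulate counterfactual monthly counts from the routed family.

    Per month, ``n_sims`` i.i.d. counts are drawn from Poisson(mu), from a
    moment-matched negative binomial with mean ``mu`` and size
    ``mu/(phi-1)`` (variance exactly ``phi*mu``) for the over-dispersed
    Poisson family, or from a negative binomial with size ``theta``.  Draws
    are conditional on the fitted mean by default; with
    ``propagate_coef_uncertainty`` the coefficients are resampled
    asymptotic-normally per simulation before drawing.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    months = pd.PeriodIndex([parse_month(m) for m in months], freq="M")
    rng = np.random.default_rng(seed)
    mu = fit.predict_mean(months)
    if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
        raise ValueError(f"non-positive or non-finite predicted mean for {fit.entity_id}")

    if propagate_coef_uncertainty:
        if fit.coef_cov is None:
            raise ValueError("coefficient covariance unavailable")
        betas = rng.multivariate_normal(fit.coef, fit.coef_cov, size=n_sims)
        X = build_design_matrix(fit.spec, months, fit.origin)
        mean_matrix = np.exp(X @ betas.T)  # (n_months, n_sims)
    else:
        mean_matrix = np.repeat(mu[:, None], n_sims, axis=1)

    if fit.family == "poisson":
        draws = rng.poisson(mean_matrix)
    elif fit.family == "overdispersed_poisson":
        size = mean_matrix / (fit.family_param - 1.0)
        draws = rng.negative_binomial(size, size / (size + mean_matrix))
    elif fit.family == "negbin":
        theta = fit.family_param
        draws = rng.negative_binomial(theta, theta / (theta + mean_matrix))
    else:
        raise ValueError(f"unknown family {fit.family!r}")
    return CounterfactualDraws(entity_id=fit.entity_id, months=months,
                               mu=mu, draws=draws.astype(np.int64))


@dataclass(frozen=True)
class PredictionInterval:
    month: pd.Period
    lower: int
    upper: int
    level: float = 0.95


def prediction_intervals(draws: CounterfactualDraws, level: float = 0.95):
    """Per-month order-statistic prediction intervals (inverted-ECDF rule).

    With ``S`` sorted draws and ``alpha = 1 - level``, the bounds are the
    ``ceil(alpha/2 * S)``-th and ``ceil((1 - alpha/2) * S)``-th smallest
    draws — always attained integer counts, no interpolation.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1); got {level}")
    S = draws.n_sims
    if S < 40 and level >= 0.95:
        raise ValueError("need at least 40 draws for a 95% interval")
    alpha = 1.0 - level
    lo_idx = max(math.ceil(alpha / 2 * S), 1) - 1
    hi_idx = math.ceil((1 - alpha / 2) * S) - 1
    out = []
    for i, m in enumerate(draws.months):
        srt = np.sort(draws.draws[i])
        out.append(PredictionInterval(month=m, lower=int(srt[lo_idx]),
                                      upper=int(srt[hi_idx]), level=level))
    return out
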