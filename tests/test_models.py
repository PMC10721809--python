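"""Candidate models: enumeration, design matrices, GLM fitting (with an
independent likelihood-maximization oracle), blocked CV, dispersion routing,
Monte-Carlo draws and prediction intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from careshift._months import month_range
from careshift.models import (
    CandidateModelSpec, CounterfactualDraws, FitError, FittedCounterfactual,
    assess_dispersion, blocked_cv_select, build_design_matrix, enumerate_candidates,
    fit_count_glm, fit_entity, prediction_intervals, rmspe, simulate_counterfactual,
)

MONTHS_3Y = month_range("2017-01", "2019-12")


def _make_fit(coef, family="poisson", family_param=None, spec=None):
    return FittedCounterfactual(
        entity_id="e", spec=spec or CandidateModelSpec("none", False, 0),
        coef=np.asarray(coef, dtype=float), coef_cov=None, family=family,
        family_param=family_param, phi_hat=1.0, cv_mse={}, rmspe=0.0,
        origin=pd.Period("2020-01", "M"))


class TestEnumerateCandidates:
    def test_default_crossing_has_ten_specs(self):
        cands = enumerate_candidates()
        assert len(cands) == 10
        assert [c.id for c in cands] == list(range(10))
        params = [c.n_params for c in cands]
        assert params == sorted(params)  # ordered fewest to most parameters
        assert len({(c.seasonal_block, c.include_trend) for c in cands}) == 10

    def test_restricted_to_no_seasonality(self):
        cands = enumerate_candidates(seasonal_blocks=["none"])
        assert len(cands) == 2
        assert cands[0].n_params == 1 and cands[1].n_params == 2

    def test_parameter_count_arithmetic(self):
        spec = CandidateModelSpec("harmonics12_6_3", True, 0)
        assert spec.n_params == 1 + 6 + 1
        assert CandidateModelSpec("month_effects", False, 0).n_params == 12


class TestDesignMatrix:
    def test_harmonic_columns_at_reference_points(self):
        spec = CandidateModelSpec("harmonics12", False, 0)
        X = build_design_matrix(spec, MONTHS_3Y)
        assert X[0] == pytest.approx([1.0, 0.0, 1.0])          # t=0: sin 0, cos 1
        assert X[6] == pytest.approx([1.0, 0.0, -1.0], abs=1e-12)  # t=6: half period

    def test_january_is_month_effect_reference(self):
        spec = CandidateModelSpec("month_effects", False, 0)
        X = build_design_matrix(spec, MONTHS_3Y)
        assert X.shape == (36, 12)
        assert np.all(X[0, 1:] == 0)        # January row: all indicators zero
        assert X[1, 1] == 1.0               # February indicator

    def test_trend_is_zero_based_year_index_from_origin(self):
        spec = CandidateModelSpec("none", True, 0)
        X = build_design_matrix(spec, month_range("2020-01", "2021-12"),
                                origin="2017-01")
        assert X[0, 1] == 3.0 and X[-1, 1] == 4.0

    def test_empty_month_range_rejected(self):
        with pytest.raises(ValueError):
            build_design_matrix(CandidateModelSpec("none", False, 0),
                                pd.PeriodIndex([], freq="M"))


class TestFitCountGlm:
    def test_intercept_only_recovers_log_mean(self):
        X = np.ones((36, 1))
        beta = fit_count_glm(X, np.full(36, 50))
        assert beta[0] == pytest.approx(np.log(50), abs=1e-8)
        beta = fit_count_glm(np.ones((2, 1)), np.array([40, 60]))
        assert beta[0] == pytest.approx(np.log(50), abs=1e-8)

    def test_matches_generic_likelihood_maximization(self):
        # independent oracle: BFGS on the Poisson log-likelihood
        rng = np.random.default_rng(7)
        spec = CandidateModelSpec("none", True, 0)
        X = build_design_matrix(spec, MONTHS_3Y)
        y = rng.poisson(np.exp(4.0 + 0.15 * X[:, 1]))
        beta = fit_count_glm(X, y)

        def negll(b):
            eta = X @ b
            return -(y @ eta - np.exp(eta).sum())

        def grad(b):
            return -(X.T @ (y - np.exp(X @ b)))

        res = optimize.minimize(negll, np.zeros(2), jac=grad, method="BFGS",
                                options={"gtol": 1e-12})
        assert beta == pytest.approx(res.x, abs=1e-6)

    def test_rank_deficiency_is_a_fit_failure(self):
        X = np.column_stack([np.ones(12), np.ones(12)])
        with pytest.raises(FitError):
            fit_count_glm(X, np.arange(12))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_count_glm(np.ones((3, 1)), np.array([1, -2, 3]))


class TestBlockedCV:
    def test_constant_series_selects_intercept_only(self):
        counts = pd.Series(np.full(36, 50), index=MONTHS_3Y)
        selected, cv_mse, holdout = blocked_cv_select(counts)
        assert selected.seasonal_block == "none" and not selected.include_trend
        assert set(cv_mse) == set(range(10))
        assert holdout == pytest.approx(np.full(36, 50.0), rel=1e-6)

    def test_equal_scores_break_toward_fewer_parameters(self):
        # every candidate fits a constant series exactly (all scores 0),
        # so the tie-break must pick the 1-parameter model
        counts = pd.Series(np.full(36, 80), index=MONTHS_3Y)
        selected, cv_mse, _ = blocked_cv_select(counts)
        assert min(cv_mse.values()) == pytest.approx(0.0, abs=1e-12)
        assert selected.n_params == 1

    def test_planted_annual_structure_recovered(self):
        rng = np.random.default_rng(11)
        t = np.arange(36.0)
        years = t // 12
        for _ in range(5):
            mean = np.exp(5.0 + 0.1 * years + 0.4 * np.sin(2 * np.pi * t / 12 + 1.0))
            counts = pd.Series(rng.poisson(mean), index=MONTHS_3Y)
            selected, _, _ = blocked_cv_select(counts)
            assert selected.has_12m_seasonality

    def test_requires_two_calendar_years(self):
        short = pd.Series(np.arange(12), index=month_range("2019-01", "2019-12"))
        with pytest.raises(ValueError):
            blocked_cv_select(short)


class TestDispersion:
    def test_zero_residuals_stay_poisson(self):
        mu = np.full(36, 100.0)
        family, param, phi = assess_dispersion(mu.copy(), mu, n_params=1)
        assert family == "poisson" and param is None and phi == 0.0

    def test_strong_negbin_routes_away_from_poisson(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = rng.negative_binomial(5, 5 / 105, 36).astype(float)
            family, param, phi = assess_dispersion(y, np.full(36, y.mean()), 1)
            assert family != "poisson" and phi > 1.2
            if family == "negbin":
                assert param > 0

    def test_needs_residual_degrees_of_freedom(self):
        with pytest.raises(ValueError):
            assess_dispersion(np.ones(3), np.ones(3), n_params=3)


class TestSimulateCounterfactual:
    MONTH = month_range("2020-01", "2020-01")

    def test_poisson_draw_moments(self):
        fit = _make_fit([np.log(100)])
        draws = simulate_counterfactual(fit, self.MONTH, 100_000, seed=5)
        x = draws.draws[0]
        assert abs(x.mean() - 100) < 0.3
        assert abs(x.var(ddof=1) - 100) < 5
        assert x.dtype == np.int64 and x.min() >= 0

    def test_overdispersed_poisson_variance_is_phi_mu(self):
        fit = _make_fit([np.log(100)], family="overdispersed_poisson", family_param=4.0)
        x = simulate_counterfactual(fit, self.MONTH, 100_000, seed=5).draws[0]
        assert abs(x.mean() - 100) < 0.7
        assert abs(x.var(ddof=1) - 400) < 20

    def test_negbin_variance_is_mu_plus_mu2_over_theta(self):
        fit = _make_fit([np.log(100)], family="negbin", family_param=5.0)
        x = simulate_counterfactual(fit, self.MONTH, 200_000, seed=5).draws[0]
        assert abs(x.var(ddof=1) - 2100) < 100

    def test_deterministic_given_seed(self):
        fit = _make_fit([np.log(50)])
        one = simulate_counterfactual(fit, self.MONTH, 1, seed=9).draws
        two = simulate_counterfactual(fit, self.MONTH, 1, seed=9).draws
        assert np.array_equal(one, two)

    def test_propagated_uncertainty_widens_draws(self):
        fit = _make_fit([np.log(100)])
        fit.coef_cov = np.array([[0.01]])
        plain = simulate_counterfactual(fit, self.MONTH, 50_000, seed=2)
        wide = simulate_counterfactual(fit, self.MONTH, 50_000, seed=2,
                                       propagate_coef_uncertainty=True)
        assert wide.draws.var() > plain.draws.var() * 1.5  # + mu^2 * 0.01 term


class TestPredictionIntervals:
    def _draws(self, values):
        values = np.asarray(values)
        return CounterfactualDraws(entity_id="e", months=month_range("2020-01", "2020-01"),
                                   mu=np.array([values.mean()]),
                                   draws=values[None, :])

    def test_order_statistic_convention(self):
        pis = prediction_intervals(self._draws(np.arange(1, 101)), level=0.95)
        assert (pis[0].lower, pis[0].upper) == (3, 98)

    def test_degenerate_draws(self):
        pis = prediction_intervals(self._draws(np.full(100, 100)), level=0.95)
        assert (pis[0].lower, pis[0].upper) == (100, 100)

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.5])
    def test_invalid_level_rejected(self, level):
        with pytest.raises(ValueError):
            prediction_intervals(self._draws(np.arange(100)), level=level)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            prediction_intervals(self._draws(np.arange(20)), level=0.95)

    def test_wider_level_widens_interval(self):
        draws = self._draws(np.random.default_rng(0).poisson(100, 10_000))
        lo90, hi90 = (p := prediction_intervals(draws, 0.90)[0]).lower, p.upper
        lo99, hi99 = (p := prediction_intervals(draws, 0.99)[0]).lower, p.upper
        assert lo99 <= lo90 and hi99 >= hi90

    def test_width_monotone_in_dispersion_parameters(self):
        months = month_range("2020-01", "2020-01")

        def width(family, param):
            fit = _make_fit([np.log(100)], family=family, family_param=param)
            pi = prediction_intervals(simulate_counterfactual(fit, months, 50_000,
                                                              seed=3))[0]
            return pi.upper - pi.lower

        assert width("overdispersed_poisson", 4.0) > width("overdispersed_poisson", 2.0)
        assert width("negbin", 5.0) > width("negbin", 50.0)


class TestRmspe:
    @pytest.mark.parametrize("obs, pred, expected", [
        ([100, 100], [90, 110], 0.10),
        ([100, 200], [100, 200], 0.0),
        ([100], [87.5], 0.125),   # the exclusion-rule boundary
    ])
    def test_arithmetic(self, obs, pred, expected):
        assert rmspe(np.array(obs), np.array(pred)) == pytest.approx(expected)

    def test_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            rmspe(np.array([0, 10]), np.array([1.0, 10.0]))


class TestFitEntity:
    def test_full_path_on_seasonal_poisson(self):
        rng = np.random.default_rng(21)
        t = np.arange(36.0)
        mean = np.exp(5.0 + 0.3 * np.sin(2 * np.pi * t / 12))
        counts = pd.Series(rng.poisson(mean), index=MONTHS_3Y)
        fit = fit_entity(counts, "ent")
        assert fit.entity_id == "ent"
        assert fit.spec.has_12m_seasonality
        assert fit.rmspe < 0.125
        mu = fit.predict_mean(month_range("2020-01", "2020-12"))
        assert np.all(mu > 0)
        # round-trips through the JSON representation
        back = FittedCounterfactual.from_dict(fit.to_dict())
        assert back.spec == fit.spec
        assert back.coef == pytest.approx(fit.coef)
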