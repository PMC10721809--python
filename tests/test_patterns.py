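"""Cross-entity patterns: quarterly matrices, complete-linkage clustering,
heatmap intensities, and the severity hypothesis tests (with enumeration and
closed-form oracles)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from careshift.deviations import DeviationEstimate
from careshift.patterns import (
    DEFAULT_QUARTERS, heatmap_intensity, hierarchical_cluster, kruskal_wallis,
    pearson_correlation, quarter_of, quarterly_matrix, rank_sum_test,
    severity_regression,
)


def _qest(entity, quarter, delta):
    return DeviationEstimate(entity_id=entity, timeframe_type="quarter",
                             timeframe=quarter, delta=delta, ci_lower=delta - 0.1,
                             ci_upper=delta + 0.1, p_value=0.5, n_sims=100,
                             p_adjusted=0.5)


class TestQuarterlyMatrix:
    def test_calendar_quarter_mapping(self):
        assert quarter_of("2020-07") == "2020Q3"
        assert quarter_of("2021-12") == "2021Q4"
        assert quarter_of("2020-06") == "2020Q2"  # June is outside the clustered quarters

    def test_shape_and_column_order(self):
        ests = [_qest(f"E{i}", q, 0.1 * i) for i in range(10) for q in DEFAULT_QUARTERS]
        mat = quarterly_matrix(ests)
        assert mat.shape == (10, 6)
        assert list(mat.columns) == list(DEFAULT_QUARTERS)

    def test_missing_cell_error_names_entity_and_quarter(self):
        ests = [_qest("A", q, 0.0) for q in DEFAULT_QUARTERS]
        ests += [_qest("B", q, 0.0) for q in DEFAULT_QUARTERS if q != "2021Q2"]
        with pytest.raises(ValueError, match="B.*2021Q2"):
            quarterly_matrix(ests)


class TestHierarchicalCluster:
    def test_two_well_separated_pairs(self):
        mat = pd.DataFrame([(0, 0), (0, 0.1), (10, 10), (10, 10.1)],
                           index=list("abcd"))
        res = hierarchical_cluster(mat, k=2)
        labels = res.labels
        assert labels["a"] == labels["b"] != labels["c"]
        assert labels["c"] == labels["d"]
        assert sorted(res.leaf_order.tolist()) == [0, 1, 2, 3]

    def test_identical_rows_merge_at_height_zero(self):
        mat = pd.DataFrame([(1.0, 2.0)] * 3, index=list("xyz"))
        res = hierarchical_cluster(mat, k=1)
        assert res.linkage[0, 2] == 0.0
        assert np.all(np.diff(res.linkage[:, 2]) >= 0)  # complete linkage is monotone

    def test_newick_export_contains_all_leaves(self):
        mat = pd.DataFrame(np.arange(8.0).reshape(4, 2), index=list("abcd"))
        nwk = hierarchical_cluster(mat, k=2).newick()
        assert nwk.endswith(";")
        for leaf in "abcd":
            assert leaf in nwk

    def test_invalid_inputs(self):
        mat = pd.DataFrame([(0.0, 1.0), (1.0, 0.0)])
        with pytest.raises(ValueError):
            hierarchical_cluster(mat, k=3)
        with pytest.raises(ValueError):
            hierarchical_cluster(mat.iloc[:1], k=1)
        with pytest.raises(ValueError):
            hierarchical_cluster(mat.replace(1.0, np.nan), k=1)


class TestHeatmapIntensity:
    @pytest.mark.parametrize("delta, p, expected", [
        (-0.5, 0.01, -1.0),   # 0.5 * 2 with log10, negative sign kept
        (0.7, 1.0, 0.0),      # -log10(1) = 0 regardless of delta
        (0.0, 0.2, 0.0),
    ])
    def test_signed_product(self, delta, p, expected):
        assert heatmap_intensity(delta, p) == pytest.approx(expected)

    def test_odd_in_delta_and_monotone_in_significance(self):
        assert heatmap_intensity(-0.4, 0.03) == -heatmap_intensity(0.4, 0.03)
        ps = [0.5, 0.1, 0.01, 1e-12]   # last one exercises the floor
        vals = [heatmap_intensity(0.4, p) for p in ps]
        assert vals == sorted(vals)
        assert np.isfinite(vals[-1])

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            heatmap_intensity(0.1, 0.0)


class TestSeverityRegression:
    def test_exact_line(self):
        res = severity_regression([-0.8, -0.7, -0.6], [1, 2, 3])
        assert res.slope == pytest.approx(0.1)
        assert res.test == "ols_slope"

    def test_flat_response_has_zero_slope(self):
        res = severity_regression([-0.5, -0.5, -0.5, -0.5], [1, 2, 3, 4])
        assert res.slope == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.integers(1, 6, 30).astype(float)
        y = -0.5 + 0.05 * x + rng.normal(0, 0.1, 30)
        res = severity_regression(y, x)
        # closed form: slope = Sxy/Sxx, t against t(n-2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        resid = y - (y.mean() + slope * (x - x.mean()))
        se = np.sqrt(resid @ resid / (len(x) - 2) / np.sum((x - x.mean()) ** 2))
        p = 2 * stats.t.sf(abs(slope / se), len(x) - 2)
        assert res.slope == pytest.approx(slope)
        assert res.p_value == pytest.approx(p)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError):
            severity_regression([0.1, 0.2, 0.3], [2, 2, 2])


class TestRankSum:
    def test_complete_separation_small_sample(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 orderings as extreme

    def test_identical_singletons(self):
        assert rank_sum_test([1.0], [1.0]).p_value == 1.0

    @pytest.mark.parametrize("m, n", [(2, 3), (3, 3), (4, 5), (5, 6), (6, 6)])
    def test_exact_p_matches_scipy_enumeration(self, m, n):
        rng = np.random.default_rng(m * 10 + n)
        a, b = rng.permutation(np.arange(1.0, m + n + 1))[:m], None
        vals = rng.permutation(np.arange(1.0, m + n + 1))
        a, b = vals[:m], vals[m:]
        ours = rank_sum_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(1)
        vals = rng.permutation(np.arange(1.0, 14.0))  # m+n=13 -> asymptotic branch
        a, b = vals[:6], vals[6:]
        ours = rank_sum_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert abs(ours.p_value - ref.pvalue) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestKruskalWallis:
    def test_hand_computed_h(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.p_value == pytest.approx(stats.chi2.sf(7.2, 2))

    def test_identical_groups_have_zero_h(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0)

    def test_all_values_tied_degenerates(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_matches_rank_formula_on_random_groups(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(size=rng.integers(3, 7)) for _ in range(3)]
        res = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        start, h = 0, 0.0
        for g in groups:
            r = ranks[start:start + len(g)]
            h += len(g) * (r.mean() - (n + 1) / 2) ** 2
            start += len(g)
        h *= 12 / (n * (n + 1))
        assert res.statistic == pytest.approx(h)  # no ties in normal draws

    def test_needs_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


def test_pearson_correlation_matches_scipy():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=20), rng.normal(size=20)
    r, p = pearson_correlation(x, y)
    ref = stats.pearsonr(x, y)
    assert (r, p) == pytest.approx((ref.statistic, ref.pvalue))
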