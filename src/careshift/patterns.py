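"""Cross-entity pattern analyses of deviation trajectories.

Builds the entities x quarters deviation matrix for the post-acute window,
clusters it hierarchically (Euclidean distance, complete linkage), scores
heatmap cells by ``|delta| * -log10(adjusted p)`` with the deviation's sign,
and runs the severity-association hypothesis tests: univariable OLS of
deviation on ordinal severity rank, Wilcoxon rank-sum (Mann-Whitney U)
between vision-threatening and non-vision-threatening groups, and
Kruskal-Wallis across severity strata.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ClusterResult",
    "SeverityTestResult",
    "DEFAULT_QUARTERS",
    "quarter_of",
    "quarterly_matrix",
    "hierarchical_cluster",
    "heatmap_intensity",
    "severity_regression",
    "rank_sum_test",
    "kruskal_wallis",
    "pearson_correlation",
]

# post-acute quarters, chronological
DEFAULT_QUARTERS = ("2020Q3", "2020Q4", "2021Q1", "2021Q2", "2021Q3", "2021Q4")

_P_FLOOR = 1e-10  # adjusted p floored here before the log so intensities stay finite


def quarter_of(month) -> str:
    """Calendar quarter label (e.g. 2020-07 -> '2020Q3')."""
    m = pd.Period(month, freq="M")
    return f"{m.year}Q{(m.month - 1) // 3 + 1}"


def quarterly_matrix(estimates, quarters=DEFAULT_QUARTERS) -> pd.DataFrame:
    """Entities x quarters matrix of point-estimate deviations.

    ``estimates`` are quarter-timeframe :class:`DeviationEstimate` objects;
    every entity must have a value for every requested quarter.
    """
    rows = {}
    for est in estimates:
        rows.setdefault(est.entity_id, {})[est.timeframe] = est.delta
    entities = sorted(rows)
    for ent in entities:
        for q in quarters:
            if q not in rows[ent]:
                raise ValueError(f"entity {ent!r} is missing quarter {q}")
    data = [[rows[ent][q] for q in quarters] for ent in entities]
    return pd.DataFrame(data, index=entities, columns=list(quarters))


@dataclass
class ClusterResult:
    """Agglomerative clustering of deviation trajectories."""

    linkage: np.ndarray          # scipy linkage matrix (merge children + heights)
    leaf_order: np.ndarray       # dendrogram leaf permutation
    labels: pd.Series            # entity -> cluster label (1..k)
    k: int
    distance: str = "euclidean"
    linkage_method: str = "complete"

    def newick(self) -> str:
        """Dendrogram as a Newick string with merge-height branch lengths."""
        tree = hierarchy.to_tree(self.linkage)
        names = list(self.labels.index)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{names[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hierarchical_cluster(matrix: pd.DataFrame, k: int) -> ClusterResult:
    """Complete-linkage Euclidean clustering, cut into ``k`` groups."""
    if isinstance(matrix, pd.DataFrame):
        values, index = matrix.to_numpy(dtype=float), matrix.index
    else:
        values = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(len(values))
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if np.any(~np.isfinite(values)):
        raise ValueError("matrix contains missing or non-finite values")
    if not 1 <= k <= values.shape[0]:
        raise ValueError(f"k={k} outside 1..{values.shape[0]}")
    Z = hierarchy.linkage(pdist(values, metric="euclidean"), method="complete")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    leaves = hierarchy.leaves_list(Z)
    return ClusterResult(linkage=Z, leaf_order=leaves,
                         labels=pd.Series(labels, index=index, name="cluster"), k=k)


def heatmap_intensity(delta: float, p_adjusted: float) -> float:
    """Signed display intensity ``sign(delta) * |delta| * -log10(p_adj)``."""
    if p_adjusted <= 0:
        raise ValueError("adjusted p-value must be positive")
    return float(np.sign(delta) * abs(delta) * -np.log10(max(p_adjusted, _P_FLOOR)))


@dataclass(frozen=True)
class SeverityTestResult:
    test: str            # "ols_slope" | "wilcoxon_rank_sum" | "kruskal_wallis"
    statistic: float
    p_value: float
    n: int
    slope: float | None = None

    def to_dict(self) -> dict:
        d = {"test": self.test, "statistic": self.statistic,
             "p_value": self.p_value, "n": self.n}
        if self.slope is not None:
            d["slope"] = self.slope
        return d


def severity_regression(deviations, ranks) -> SeverityTestResult:
    """Univariable OLS of deviation on ordinal severity rank (1..5)."""
    y = np.asarray(deviations, dtype=float)
    x = np.asarray(ranks, dtype=float)
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("need >= 3 paired (deviation, rank) observations")
    if np.ptp(x) == 0:
        raise ValueError("severity ranks have zero variance")
    if np.ptp(y) == 0:  # perfectly flat response: zero slope, no evidence
        return SeverityTestResult("ols_slope", 0.0, 1.0, len(y), slope=0.0)
    res = stats.linregress(x, y)
    if res.stderr == 0 or not np.isfinite(res.stderr):
        p = 1.0 if res.slope == 0 else 0.0
        t_stat = float("inf") if res.slope != 0 else 0.0
        return SeverityTestResult("ols_slope", t_stat, p, len(y), slope=float(res.slope))
    t_stat = res.slope / res.stderr
    return SeverityTestResult("ols_slope", float(t_stat), float(res.pvalue),
                              len(y), slope=float(res.slope))


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by full enumeration of rank assignments (no ties)."""
    m, n = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    mean_u = m * n / 2.0
    us = []
    for combo in itertools.combinations(range(m + n), m):
        r_a = ranks[list(combo)].sum()
        us.append(r_a - m * (m + 1) / 2.0)
    us = np.asarray(us)
    return float(np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12))


def rank_sum_test(group_a, group_b) -> SeverityTestResult:
    """Wilcoxon rank-sum / Mann-Whitney U test between two groups.

    Exact two-sided p by enumeration for small samples (m + n <= 12, no
    ties); otherwise the normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    u = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic").statistic)
    if np.ptp(pooled) == 0:
        p = 1.0  # no separation at all; the normal approximation degenerates
    elif len(pooled) <= 12 and no_ties:
        p = _exact_rank_sum_p(a, b, u)
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic").pvalue)
    return SeverityTestResult("wilcoxon_rank_sum", u, min(p, 1.0), len(pooled))


def kruskal_wallis(groups) -> SeverityTestResult:
    """Kruskal-Wallis H test across >= 2 groups (tie-corrected).

    When every value across all groups is identical the statistic is
    undefined after tie correction; the test degenerates to H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return SeverityTestResult("kruskal_wallis", 0.0, 1.0, len(pooled))
    h, p = stats.kruskal(*groups)
    return SeverityTestResult("kruskal_wallis", float(h), float(p), len(pooled))


def pearson_correlation(x, y) -> tuple:
    """Convenience Pearson correlation between paired deviation summaries."""
    r, p = stats.pearsonr(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return float(r), float(p)
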