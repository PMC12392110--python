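"""Nonparametric group statistics for SLE metric tables.

The pipeline mirrors the standard slice-electrophysiology workflow: a
Fisher exact test for 2x2 contingency comparisons (e.g. how many slices
show >2-min pauses under each disinhibition protocol), a Kruskal-Wallis
omnibus test across experimental groups, and Dunn's rank-based post hoc test
for an explicit family of pairwise contrasts with Holm-Bonferroni step-down
correction.  Significance annotations use the conventional thresholds
(* p < 0.05, ** p < 0.01, *** p < 0.001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "PairwiseComparison",
    "GroupComparisonResult",
    "fisher_exact",
    "kruskal_wallis",
    "dunn_holm",
    "compare_metric_across_groups",
    "stars",
]


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] with optional row/column labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("yes", "no")

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("table must contain at least one observation")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float
    stars: str


@dataclass
class GroupComparisonResult:
    statistic: float
    p_value: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pair": f"{c.group_a}:{c.group_b}",
                    "z": c.z,
                    "p_raw": c.p_raw,
                    "p_adj": c.p_adjusted,
                    "stars": c.stars,
                }
                for c in self.pairwise
            ]
        )


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test: ``(p_value, odds_ratio)``.

    The p-value sums hypergeometric probabilities of all margin-preserving
    tables no more probable than the observed one; the odds ratio is the
    sample odds ratio a*d / (b*c) (infinite when b*c = 0).
    """
    arr = table.as_array()
    res = sst.fisher_exact(arr, alternative="two-sided")
    bc = table.b * table.c
    odds = float("inf") if bc == 0 else table.a * table.d / bc
    return float(res.pvalue), odds


def kruskal_wallis(groups: list[np.ndarray], method: str = "chi2") -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its p-value.

    ``method='chi2'`` (default) uses the chi-squared approximation with k-1
    degrees of freedom; ``method='exact'`` enumerates the permutation null of
    H over all assignments of the pooled observations to the groups, which is
    feasible (and preferable) for very small samples.  When every observation
    is identical the statistic is defined as 0 with p = 1 (rather than
    erroring on the degenerate tie correction).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sst.kruskal(*arrays)
    if method == "exact":
        p = _kw_exact_p(arrays, float(h))
    elif method != "chi2":
        raise ValueError("method must be 'chi2' or 'exact'")
    return float(h), float(p)


def _kw_exact_p(arrays: list[np.ndarray], h_obs: float) -> float:
    """P(H >= observed) under the exact permutation null (small n)."""
    from itertools import combinations

    pooled = np.concatenate(arrays)
    n = pooled.size
    if n > 12:
        raise ValueError("exact method is limited to small samples (n <= 12)")
    sizes = [a.size for a in arrays]
    ranks = sst.rankdata(pooled)
    tie = _tie_factor(pooled, n)

    def h_from(groups_idx: list[np.ndarray]) -> float:
        h = 12.0 / (n * (n + 1)) * sum(
            ranks[idx].sum() ** 2 / idx.size for idx in groups_idx
        ) - 3 * (n + 1)
        return h / tie if tie > 0 else 0.0

    count = total = 0

    def rec(remaining: np.ndarray, k: int, chosen: list[np.ndarray]):
        nonlocal count, total
        if k == len(sizes) - 1:
            groups_idx = chosen + [remaining]
            total += 1
            if h_from(groups_idx) >= h_obs - 1e-12:
                count += 1
            return
        for combo in combinations(range(remaining.size), sizes[k]):
            sel = remaining[list(combo)]
            rest = np.delete(remaining, list(combo))
            rec(rest, k + 1, chosen + [sel])

    rec(np.arange(n), 0, [])
    return count / total


def _tie_factor(pooled: np.ndarray, n: int) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - np.sum(counts**3 - counts) / (n**3 - n)


def _dunn_z(groups: dict[str, np.ndarray], a: str, b: str) -> float:
    """Dunn z-statistic for one pair from pooled ranks with tie correction."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = sst.rankdata(pooled)
    n_total = pooled.size
    mean_ranks = {}
    start = 0
    for g in labels:
        n_g = groups[g].size
        mean_ranks[g] = ranks[start : start + n_g].mean()
        start += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term
    na, nb = groups[a].size, groups[b].size
    se = np.sqrt(var_unit * (1.0 / na + 1.0 / nb))
    if se == 0:
        return 0.0
    return (mean_ranks[a] - mean_ranks[b]) / se


def dunn_holm(
    groups: dict[str, np.ndarray],
    pairs: list[tuple[str, str]] | None = None,
) -> GroupComparisonResult:
    """Kruskal-Wallis omnibus plus Dunn pairwise z-tests with Holm correction.

    ``pairs`` names the tested family explicitly (the contrasts actually
    reported); it defaults to all pairwise combinations.  Dunn p-values are
    two-sided normal tail probabilities; the Holm-Bonferroni step-down is
    applied over the requested family only.
    """
    labels = list(groups)
    if pairs is None:
        pairs = [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    for a, b in pairs:
        if a not in groups or b not in groups:
            raise ValueError(f"unknown group label in pair ({a}, {b})")
    groups = {g: np.asarray(v, dtype=np.float64) for g, v in groups.items()}
    h, p_omni = kruskal_wallis(list(groups.values()))
    zs = [_dunn_z(groups, a, b) for a, b in pairs]
    p_raw = [2.0 * sst.norm.sf(abs(z)) for z in zs]
    if p_raw:
        _, p_adj, _, _ = multipletests(p_raw, method="holm")
    else:
        p_adj = []
    pairwise = [
        PairwiseComparison(a, b, float(z), float(pr), float(pa), stars(pa))
        for (a, b), z, pr, pa in zip(pairs, zs, p_raw, p_adj)
    ]
    return GroupComparisonResult(h, p_omni, pairwise)


def compare_metric_across_groups(
    table: pd.DataFrame,
    metric: str,
    grouping: str = "group",
    pairs: list[tuple[str, str]] | None = None,
) -> GroupComparisonResult:
    """Kruskal-Wallis + Dunn/Holm on one metric column of a tidy table.

    Rows with a missing metric value are excluded (with a logged count);
    groups left empty after exclusion are dropped from the comparison.
    """
    if metric not in table.columns:
        raise KeyError(f"metric column {metric!r} absent from table")
    if grouping not in table.columns:
        raise KeyError(f"grouping column {grouping!r} absent from table")
    n_missing = int(table[metric].isna().sum())
    if n_missing:
        logger.info("excluding %d row(s) with missing %s", n_missing, metric)
    clean = table.dropna(subset=[metric])
    groups = {
        str(g): sub[metric].to_numpy(dtype=np.float64)
        for g, sub in clean.groupby(grouping, sort=True)
        if len(sub) > 0
    }
    if len(groups) < 2:
        raise ValueError("fewer than two non-empty groups after exclusions")
    if pairs is not None:
        pairs = [(a, b) for a, b in pairs if a in groups and b in groups]
    return dunn_holm(groups, pairs)
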