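"""Fisher exact, Kruskal-Wallis, Dunn/Holm: contracts and enumeration
oracles."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from sleseg.stats import (
    ContingencyTable2x2,
    compare_metric_across_groups,
    dunn_holm,
    fisher_exact,
    kruskal_wallis,
    stars,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def fisher_enumeration(a, b, c, d):
    """Exact two-sided Fisher p by rational hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if pmf(x) <= p_obs:
            total += pmf(x)
    return float(total)


def rank_average(values):
    """Average ranks, implemented independently of scipy."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def h_statistic(groups):
    pooled = [v for g in groups for v in g]
    ranks = rank_average(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start : start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    t = sum(c**3 - c for c in ties.values())
    corr = 1 - t / (n**3 - n)
    return h / corr if corr > 0 else 0.0


def kw_permutation_p(groups):
    """Exact permutation p-value of the H statistic (small n only)."""
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    h_obs = h_statistic(groups)
    count = total = 0
    for perm in itertools.permutations(pooled):
        regrouped = []
        start = 0
        for s in sizes:
            regrouped.append(list(perm[start : start + s]))
            start += s
        total += 1
        if h_statistic(regrouped) >= h_obs - 1e-12:
            count += 1
    return count / total


def holm_by_hand(p_raw):
    m = len(p_raw)
    order = sorted(range(m), key=lambda i: p_raw[i])
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        val = min(1.0, (m - rank) * p_raw[i])
        running = max(running, val)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


class TestFisher:
    def test_model_comparison_table(self):
        """Pauses >2 min: 10/18 slices vs 1/27 slices -> p < 0.001."""
        p, odds = fisher_exact(ContingencyTable2x2(10, 8, 1, 26))
        assert p < 0.001
        assert p == pytest.approx(fisher_enumeration(10, 8, 1, 26), abs=1e-12)
        assert odds == pytest.approx(10 * 26 / 8)

    def test_no_association(self):
        p, odds = fisher_exact(ContingencyTable2x2(5, 5, 5, 5))
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_diagonal_table_third(self):
        p, odds = fisher_exact(ContingencyTable2x2(2, 0, 0, 2))
        assert p == pytest.approx(1 / 3)
        assert odds == float("inf")

    def test_matches_enumeration_for_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 11, size=4)
            if a + b + c + d == 0:
                continue
            p, _ = fisher_exact(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            assert p == pytest.approx(fisher_enumeration(a, b, c, d), abs=1e-9)

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 1, 1, 1)


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_equal_defined_as_zero(self):
        h, p = kruskal_wallis([np.array([5.0, 5.0]), np.array([5.0, 5.0])])
        assert h == 0.0
        assert p == 1.0

    def test_h_matches_independent_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            groups = [rng.integers(0, 6, size=rng.integers(2, 5)).astype(float) for _ in range(3)]
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(h_statistic([list(g) for g in groups]), abs=1e-9)

    def test_exact_permutation_oracle_max_separation(self):
        groups = [[1.0, 2.0, 3.0], [101.0, 102.0, 103.0]]
        h, p_exact = kruskal_wallis([np.array(g) for g in groups], method="exact")
        assert h == pytest.approx(h_statistic(groups), abs=1e-9)
        # the permutation p of this 6-value instance is 2 / C(6,3)
        assert p_exact == pytest.approx(0.1)
        assert p_exact == pytest.approx(kw_permutation_p(groups))

    def test_exact_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            groups = [list(rng.integers(0, 4, size=3).astype(float)) for _ in range(2)]
            _, p_exact = kruskal_wallis([np.array(g) for g in groups], method="exact")
            assert p_exact == pytest.approx(kw_permutation_p(groups), abs=1e-12)

    def test_fewer_than_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.array([1.0, 2.0])])


class TestDunnHolm:
    def test_single_pair_unadjusted(self):
        rng = np.random.default_rng(2)
        groups = {"a": rng.standard_normal(8), "b": rng.standard_normal(8) + 1}
        res = dunn_holm(groups, [("a", "b")])
        assert res.pairwise[0].p_adjusted == pytest.approx(res.pairwise[0].p_raw)

    def test_adjustment_matches_holm_by_hand(self):
        rng = np.random.default_rng(3)
        groups = {
            "a": rng.standard_normal(10),
            "b": rng.standard_normal(10) + 0.8,
            "c": rng.standard_normal(10) + 1.6,
        }
        res = dunn_holm(groups)
        raw = [c.p_raw for c in res.pairwise]
        adj = [c.p_adjusted for c in res.pairwise]
        np.testing.assert_allclose(adj, holm_by_hand(raw), atol=1e-12)
        assert all(a >= r for a, r in zip(adj, raw))
        assert all(a <= 1.0 for a in adj)

    def test_identical_raw_ps_degenerate_to_bonferroni(self):
        # symmetric design: both contrasts with the center group share |z|
        groups = {"lo": np.array([1.0, 2.0, 3.0]), "mid": np.array([4.0, 5.0, 6.0]), "hi": np.array([7.0, 8.0, 9.0])}
        res = dunn_holm(groups, [("lo", "mid"), ("mid", "hi")])
        p1, p2 = res.pairwise
        assert p1.p_raw == pytest.approx(p2.p_raw)
        assert p1.p_adjusted == pytest.approx(min(1.0, 2 * p1.p_raw))

    def test_unknown_pair_label(self):
        with pytest.raises(ValueError):
            dunn_holm({"a": np.array([1.0]), "b": np.array([2.0])}, [("a", "zzz")])

    def test_stars_thresholds(self):
        assert stars(0.2) == ""
        assert stars(0.04) == "*"
        assert stars(0.004) == "**"
        assert stars(0.0004) == "***"


class TestCompareAcrossGroups:
    def make_table(self, rng, deltas, n=12):
        rows = []
        for g, d in deltas.items():
            for i in range(n):
                rows.append({"unit_id": f"{g}{i}", "group": g, "fraction": rng.standard_normal() + d})
        return pd.DataFrame(rows)

    def test_detects_strong_shift(self):
        rng = np.random.default_rng(4)
        t = self.make_table(rng, {"ctrl": 0.0, "cnb": -3.0})
        res = compare_metric_across_groups(t, "fraction")
        assert res.p_value < 0.001
        assert res.pairwise[0].p_adjusted < 0.001

    def test_missing_values_excluded(self, caplog):
        rng = np.random.default_rng(5)
        t = self.make_table(rng, {"ctrl": 0.0, "cnb": -3.0})
        t.loc[t.index[:3], "fraction"] = np.nan
        res = compare_metric_across_groups(t, "fraction")
        assert res.p_value < 0.01

    def test_all_missing_group_dropped(self):
        rng = np.random.default_rng(6)
        t = self.make_table(rng, {"ctrl": 0.0, "cnb": -2.0, "dead": 0.0})
        t.loc[t["group"] == "dead", "fraction"] = np.nan
        res = compare_metric_across_groups(t, "fraction", pairs=[("ctrl", "cnb"), ("ctrl", "dead")])
        assert {c.group_b for c in res.pairwise} == {"cnb"}

    def test_absent_metric_column(self):
        with pytest.raises(KeyError):
            compare_metric_across_groups(pd.DataFrame({"group": ["a"]}), "fraction")
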