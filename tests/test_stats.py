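"""Nonparametric tests against independent exact-enumeration oracles.

The oracles below enumerate the full null distribution by brute force
(all sign assignments for the signed-rank tests, all group assignments
for the U test) and never call the implementation under test.
"""

from itertools import combinations

import numpy as np
import pytest

from larvasearch import (
    kruskal_wallis,
    mann_whitney_u,
    significance_stars,
    wilcoxon_one_sample,
    wilcoxon_paired,
)
from larvasearch.stats import posthoc_pairwise

# ---------------------------------------------------------------------------
# brute-force oracles


def exact_signed_rank_p(d):
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    dist = []
    for bits in range(2**n):
        signs = [(bits >> i) & 1 for i in range(n)]
        dist.append(sum(r for r, s in zip(ranks, signs) if s))
    dist = np.asarray(dist)
    p_ge = np.mean(dist >= w_obs)
    p_le = np.mean(dist <= w_obs)
    return min(1.0, 2 * min(p_ge, p_le))


def exact_mwu_p(a, b):
    """Two-sided exact U-test p by enumerating all C(n+m, n) splits."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n = a.size

    def u_of(idx):
        grp = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        return sum(np.sum(g > rest) + 0.5 * np.sum(g == rest) for g in grp)

    u_obs = u_of(range(n))
    dist = np.array([u_of(c) for c in combinations(range(pooled.size), n)])
    p_ge = np.mean(dist >= u_obs)
    p_le = np.mean(dist <= u_obs)
    return min(1.0, 2 * min(p_ge, p_le))


def kruskal_h_oracle(groups):
    """H from the rank-sum formula with tie correction, written directly."""
    pooled = np.concatenate(groups)
    N = pooled.size
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(N)
    sorted_vals = pooled[order]
    i = 0
    rank_of = np.empty(N)
    while i < N:
        j = i
        while j + 1 < N and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        rank_of[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        rsum = rank_of[start : start + len(g)].sum()
        h += rsum**2 / len(g)
        start += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return h / tie


# ---------------------------------------------------------------------------


class TestWilcoxonPaired:
    def test_all_positive_differences_n6(self):
        res = wilcoxon_paired([2.0, 2.9, 3.8, 4.7, 5.6, 7.0], [1, 2, 3, 4, 5, 6.5])
        assert res.p_value == pytest.approx(2 / 64)
        assert res.exact

    def test_identical_samples_give_p_one(self):
        with pytest.warns(UserWarning, match="all differences are zero"):
            res = wilcoxon_paired([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.p_value == 1.0
        assert res.n_dropped_zeros == 5

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        assert wilcoxon_paired(x, y).p_value == pytest.approx(
            wilcoxon_paired(y, x).p_value
        )

    def test_zero_differences_dropped(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [1.0, 1.5, 2.5, 3.1, 4.2, 5.3]
        res = wilcoxon_paired(x, y)
        assert res.n_dropped_zeros == 1
        assert res.n == 5

    def test_matches_enumeration_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for n in (5, 6, 7, 8):
            for _ in range(10):
                d = rng.normal(size=n)
                res = wilcoxon_one_sample(d)
                assert res.p_value == pytest.approx(exact_signed_rank_p(d), abs=1e-12)

    def test_shift_monotonicity(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=10)
        y = x + rng.normal(0, 0.3, size=10)
        ps = [wilcoxon_paired(x + shift, y).p_value for shift in np.arange(0, 5, 0.25)]
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))
        assert ps[-1] == pytest.approx(2 / 2**10)


class TestWilcoxonOneSample:
    def test_all_positive_scores_n6(self):
        res = wilcoxon_one_sample([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        assert res.p_value == pytest.approx(2 / 64)

    def test_pairwise_symmetric_scores(self):
        res = wilcoxon_one_sample([-3.0, 3.0, -2.0, 2.0, -1.0, 1.0])
        assert res.p_value == pytest.approx(1.0)

    def test_outlier_changes_statistic_not_null(self):
        base = [-2.0, 2.1, -1.0, 1.1, -0.5, 0.6]
        spiked = [-2.0, 50.0, -1.0, 1.1, -0.5, 0.6]
        r1, r2 = wilcoxon_one_sample(base), wilcoxon_one_sample(spiked)
        assert r1.p_value == pytest.approx(exact_signed_rank_p(base), abs=1e-12)
        assert r2.p_value == pytest.approx(exact_signed_rank_p(spiked), abs=1e-12)

    def test_nonzero_location(self):
        scores = [1.1, 1.2, 1.3, 1.4, 1.5, 1.6]
        assert wilcoxon_one_sample(scores, mu0=1.35).p_value > 0.3


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert res.statistic == 0.0

    def test_identical_groups(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_group_swap_maps_u(self):
        a, b = [1.0, 2.5, 3.0, 7.0], [2.0, 4.0, 5.0]
        r1, r2 = mann_whitney_u(a, b), mann_whitney_u(b, a)
        assert r1.statistic + r2.statistic == len(a) * len(b)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_enumeration_on_random_inputs(self):
        rng = np.random.default_rng(17)
        for na, nb in ((3, 3), (4, 5), (6, 4), (8, 8)):
            a = rng.normal(size=na)
            b = rng.normal(0.5, 1.0, size=nb)
            assert mann_whitney_u(a, b).p_value == pytest.approx(
                exact_mwu_p(a, b), abs=1e-12
            )


class TestKruskalWallis:
    def test_identical_groups_no_evidence(self):
        res = kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_h_matches_rank_formula(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(kruskal_h_oracle(groups))

    def test_h_matches_rank_formula_with_ties(self):
        rng = np.random.default_rng(3)
        groups = [rng.integers(0, 5, size=6).astype(float) for _ in range(4)]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(kruskal_h_oracle(groups))

    def test_group_order_invariant(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(size=5), rng.normal(1, 1, 5), rng.normal(2, 1, 5)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis(groups[::-1]).statistic
        assert h1 == pytest.approx(h2)

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], [2.0]])


class TestPosthoc:
    def test_no_posthoc_without_global_significance(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(size=8) for _ in range(3)]
        assert posthoc_pairwise(groups) == []

    def test_posthoc_after_clear_separation(self):
        groups = [
            np.arange(8) * 0.1,
            np.arange(8) * 0.1 + 5.0,
            np.arange(8) * 0.1 + 10.0,
        ]
        rows = posthoc_pairwise(groups, labels=["a", "b", "c"])
        assert len(rows) == 3
        assert all(r["p_adj"] >= r["p_raw"] for r in rows)
        assert {r["comparison"] for r in rows} == {"a vs b", "a vs c", "b vs c"}


class TestStars:
    @pytest.mark.parametrize(
        "p,stars", [(0.04, "*"), (0.05, "*"), (0.009, "**"), (0.0005, "***"), (0.2, "ns"), (0.001, "**")]
    )
    def test_thresholds(self, p, stars):
        assert significance_stars(p) == stars
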