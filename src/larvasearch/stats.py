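"""Nonparametric hypothesis tests used for cohort comparisons.

Only rank-based tests are used: the paired (two-sample) Wilcoxon
signed-rank test for within-larva baseline-vs-search contrasts, the
one-sample Wilcoxon signed-rank test for scores against zero, the
Mann-Whitney U test for two independent conditions, and the
Kruskal-Wallis test (with rank-based post hoc pairwise comparisons and
a family-wise correction) for three or more.  All p-values are
two-sided.  Exact null distributions are used for small samples
(signed-rank: n <= 25 without ties; U test: both groups <= 8 without
ties), otherwise a normal approximation with tie correction.

Zero differences in the signed-rank tests are dropped before ranking
(Wilcoxon's original convention); the number dropped is recorded on
the result.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "significance_stars",
    "wilcoxon_paired",
    "wilcoxon_one_sample",
    "mann_whitney_u",
    "kruskal_wallis",
    "posthoc_pairwise",
]

EXACT_WILCOXON_MAX_N = 25
EXACT_MWU_MAX_N = 8


def significance_stars(p: float) -> str:
    """Star annotation: * for p<=0.05, ** for p<=0.01, *** for p<0.001."""
    if p < 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    p_value: float
    n: int | tuple[int, ...]
    n_dropped_zeros: int = 0
    exact: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    def row(self) -> dict:
        n = self.n if isinstance(self.n, int) else "/".join(map(str, self.n))
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p": self.p_value,
            "n": n,
            "stars": self.stars,
            "exact": self.exact,
            "note": self.note,
        }


def _signed_rank(d: np.ndarray, method_name: str) -> TestResult:
    d = np.asarray(d, dtype=float)
    nz = d != 0.0
    n_zeros = int(d.size - np.count_nonzero(nz))
    d = d[nz]
    if n_zeros:
        logger.info("%s: dropped %d zero difference(s)", method_name, n_zeros)
    n = d.size
    if n == 0:
        warnings.warn(f"{method_name}: all differences are zero; p = 1", stacklevel=3)
        return TestResult(method_name, 0.0, 1.0, 0, n_dropped_zeros=n_zeros, note="all-zero")
    has_ties = np.unique(np.abs(d)).size < n
    use_exact = n <= EXACT_WILCOXON_MAX_N and not has_ties
    res = sps.wilcoxon(
        d,
        alternative="two-sided",
        method="exact" if use_exact else "approx",
        correction=False,
    )
    return TestResult(
        method_name,
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        n,
        n_dropped_zeros=n_zeros,
        exact=use_exact,
    )


def wilcoxon_paired(x, y) -> TestResult:
    """Paired Wilcoxon signed-rank test on per-larva (x, y) value pairs.

    Used for baseline-vs-search contrasts where each larva contributes
    one value per phase.  Pairs with zero difference are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 5:
        raise ValueError("paired Wilcoxon needs n >= 5 pairs")
    return _signed_rank(x - y, "wilcoxon_paired")


def wilcoxon_one_sample(scores, mu0: float = 0.0) -> TestResult:
    """One-sample Wilcoxon signed-rank test of the median against mu0.

    Used to ask whether a cohort's search scores differ from the chance
    level of zero.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 5:
        raise ValueError("one-sample Wilcoxon needs n >= 5")
    return _signed_rank(scores - mu0, "wilcoxon_one_sample")


def mann_whitney_u(group_a, group_b) -> TestResult:
    """Mann-Whitney U test for two independent cohorts (two-sided)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = max(a.size, b.size) <= EXACT_MWU_MAX_N and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return TestResult(
        "mann_whitney_u",
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        (a.size, b.size),
        exact=use_exact,
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square p) for >= 3 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis needs at least 3 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    if any(g.size < 2 for g in groups):
        warnings.warn("Kruskal-Wallis with a group of size < 2", stacklevel=2)
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        # all observations identical: H = 0 by definition, no evidence
        return TestResult(
            "kruskal_wallis", 0.0, 1.0, tuple(g.size for g in groups), note="degenerate"
        )
    res = sps.kruskal(*groups)
    return TestResult(
        "kruskal_wallis",
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        tuple(g.size for g in groups),
    )


def posthoc_pairwise(
    groups,
    labels=None,
    alpha: float = 0.05,
    method: str = "holm",
) -> list[dict]:
    """Rank-based pairwise comparisons after a significant global test.

    Runs the global Kruskal-Wallis test first; pairwise Mann-Whitney U
    tests with a family-wise correction (Holm by default, switchable to
    any method statsmodels supports) are computed only when the global
    p-value is <= alpha.  Returns tidy rows; empty if the global test is
    not significant.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    global_res = kruskal_wallis(groups)
    if global_res.p_value > alpha:
        return []
    pairs = list(combinations(range(len(groups)), 2))
    raw = [mann_whitney_u(groups[i], groups[j]) for i, j in pairs]
    reject, p_adj, _, _ = multipletests([r.p_value for r in raw], alpha=alpha, method=method)
    rows = []
    for (i, j), r, padj, rej in zip(pairs, raw, p_adj, reject):
        rows.append(
            {
                "comparison": f"{labels[i]} vs {labels[j]}",
                "method": f"mann_whitney_u+{method}",
                "statistic": r.statistic,
                "p_raw": r.p_value,
                "p_adj": float(padj),
                "reject": bool(rej),
                "stars": significance_stars(float(padj)),
            }
        )
    return rows
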