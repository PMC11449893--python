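"""Wilcoxon rank-sum testing used by all marker detectors.

Small groups (both sides <= EXACT_MAX) are tested by exact enumeration
of the permutation distribution of the rank sum, which handles ties by
mid-ranks; larger groups use the tie- and continuity-corrected normal
approximation (scipy's asymptotic Mann-Whitney U).  The permutation
distribution of the rank sum is symmetric about its mean even under
ties (the mid-rank multiset is invariant under r -> N+1-r), so the
two-sided exact p is P(|W - E[W]| >= |w - E[W]|).
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

#: Largest per-group size for which the exact path is used.
EXACT_MAX = 8


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of ``x`` vs ``y``.

    Returns ``(U, p)`` with U the Mann-Whitney statistic of ``x``.
    Degenerate pooled data (all values identical, or an empty side)
    yields p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        return np.nan, 1.0
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return n * m / 2.0, 1.0
    ranks = rankdata(pooled)
    w = ranks[:n].sum()
    u = w - n * (n + 1) / 2.0
    if n <= EXACT_MAX and m <= EXACT_MAX:
        return u, _exact_p(ranks, n)
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _exact_p(ranks: np.ndarray, n: int) -> float:
    """Exact two-sided p by enumerating all n-subsets of the mid-ranks."""
    N = len(ranks)
    w_obs = ranks[:n].sum()
    e_w = n * (N + 1) / 2.0
    dev = abs(w_obs - e_w)
    hits = 0
    for subset in combinations(range(N), n):
        w = ranks[list(subset)].sum()
        if abs(w - e_w) >= dev - 1e-9:
            hits += 1
    return hits / comb(N, n)
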