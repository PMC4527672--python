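"""Independent brute-force oracles for the rank-sum machinery.

Everything here is implemented from first principles (hand-rolled midranks,
full enumeration of group assignments) and never calls the package under
test or scipy, so it can serve as a reference for the production code.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def midranks(pooled: list[float]) -> list[float]:
    """Average ranks (1-based) of a pooled sample, ties sharing their mean rank."""
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mean_rank = (i + j + 2) / 2.0  # 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def exact_rank_sum_p(a: list[float], b: list[float]) -> float:
    """Two-sided permutation p of the rank-sum statistic by full enumeration.

    Enumerates every assignment of the pooled midranks to group a and counts
    assignments whose rank sum deviates from its null mean by at least the
    observed amount.  For tie-free data this equals the classical exact
    two-sided Wilcoxon p (the null distribution is symmetric).
    """
    pooled = list(a) + list(b)
    ranks = midranks(pooled)
    n, n_a = len(pooled), len(a)
    w_obs = sum(ranks[:n_a])
    mu = n_a * sum(ranks) / n
    obs_dev = abs(w_obs - mu)
    hits = 0
    total = 0
    for idx in combinations(range(n), n_a):
        total += 1
        w = sum(ranks[i] for i in idx)
        if abs(w - mu) >= obs_dev - 1e-12:
            hits += 1
    return hits / total


def exact_p_null_distribution(n_a: int, n_b: int) -> dict[float, float]:
    """Null distribution {p-value: probability} of the tie-free exact test.

    Enumerates rank-sum values over all C(n, n_a) assignments of the ranks
    1..n, then maps each to its two-sided p.
    """
    n = n_a + n_b
    counts: dict[float, int] = {}
    for idx in combinations(range(1, n + 1), n_a):
        w = sum(idx)
        counts[w] = counts.get(w, 0) + 1
    total = comb(n, n_a)
    mu = n_a * (n + 1) / 2.0
    p_of_w = {
        w: sum(c for w2, c in counts.items() if abs(w2 - mu) >= abs(w - mu) - 1e-12) / total
        for w in counts
    }
    dist: dict[float, float] = {}
    for w, c in counts.items():
        dist[p_of_w[w]] = dist.get(p_of_w[w], 0.0) + c / total
    return dist


def ks_distance_from_uniform(dist: dict[float, float]) -> float:
    """Kolmogorov distance of a discrete p-value distribution from U[0,1]."""
    points = sorted(dist)
    cdf = 0.0
    worst = 0.0
    for p in points:
        worst = max(worst, abs(cdf - p))  # just below the atom
        cdf += dist[p]
        worst = max(worst, abs(cdf - p))  # at the atom
    return worst


def exact_u_counts(n_a: int, n_b: int):
    """Exact counts of the Mann-Whitney U distribution (tie-free null) via
    the textbook recurrence N(u; m, n) = N(u-n; m-1, n) + N(u; m, n-1)."""
    import numpy as np

    c = np.zeros((n_a + 1, n_b + 1, n_a * n_b + 1))
    c[0, :, 0] = 1.0
    c[:, 0, 0] = 1.0
    for m in range(1, n_a + 1):
        for n in range(1, n_b + 1):
            c[m, n, :] = c[m, n - 1, :]
            c[m, n, n:] += c[m - 1, n, : -n]
    return c[n_a, n_b]


def asymptotic_rejection_rate(n_a: int, n_b: int, alpha: float) -> float:
    """Exact null rejection probability of the two-sided normal-approximation
    rank-sum test (no continuity correction) for tie-free continuous data.

    U is distribution-free under the null, so the rate follows from the exact
    U pmf pushed through the test's own decision rule.  At small or unbalanced
    group sizes this differs measurably from the nominal alpha; it is the
    correct expectation for false-positive-rate simulations.
    """
    import numpy as np
    from math import sqrt
    from scipy.stats import norm

    counts = exact_u_counts(n_a, n_b)
    pmf = counts / counts.sum()
    us = np.arange(n_a * n_b + 1)
    mu = n_a * n_b / 2.0
    var = n_a * n_b * (n_a + n_b + 1) / 12.0
    p = np.minimum(1.0, 2.0 * norm.sf(np.abs(us - mu) / sqrt(var)))
    return float(pmf[p < alpha].sum())


def empirical_ks_uniform(pvalues) -> float:
    """KS statistic of a sample against U[0,1]."""
    xs = sorted(float(p) for p in pvalues)
    n = len(xs)
    worst = 0.0
    for i, x in enumerate(xs):
        worst = max(worst, abs((i + 1) / n - x), abs(i / n - x))
    return worst
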