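"""Censoring-aware two-sample rank testing and censored summary statistics.

Measurements below the LLOQ (or above the ULOQ) carry only ordinal
information: a "<1.71" is known to be smaller than any exact value >= 1.71
but nothing distinguishes two below-LLOQ values from each other.  All
statistics here therefore work on the *censored total preorder*

    below(b)  <  exact(x) for x >= b,      exact(x)  <  above(u) for x <= u,

with censored values at the same bound forming tie blocks.  The Wilcoxon
rank-sum (Mann-Whitney) test depends only on ranks, so it extends verbatim:
censored blocks get midranks and the usual tie correction applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .cohort import CensoredValue, Cohort, CohortError

__all__ = [
    "ComparisonResult",
    "GroupSummary",
    "rank_sum_test",
    "censored_keys",
    "censored_median",
    "censored_percentile",
    "summarize_group",
    "format_summary",
    "table1",
    "adjust_pvalues",
    "QUANTILE_METHODS",
]

#: Continuous quantile families as (alpha, beta) plotting-position constants;
#: "linear" is the ubiquitous Hyndman-Fan type 7 default.
QUANTILE_METHODS = {
    "linear": (1.0, 1.0),                     # type 7
    "interpolated_inverted_cdf": (0.0, 1.0),  # type 4
    "hazen": (0.5, 0.5),                      # type 5
    "weibull": (0.0, 0.0),                    # type 6
    "median_unbiased": (1 / 3, 1 / 3),        # type 8
    "normal_unbiased": (3 / 8, 3 / 8),        # type 9
}


def _as_censored(values: Iterable[CensoredValue | float]) -> list[CensoredValue]:
    out = []
    for v in values:
        out.append(v if isinstance(v, CensoredValue) else CensoredValue(float(v)))
    return out


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a censoring-aware two-group rank-sum test."""

    biomarker: str
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    p_value: float
    significant: bool
    degenerate: bool = False
    method: str = "asymptotic"
    median_a: Optional[CensoredValue] = None
    median_b: Optional[CensoredValue] = None
    direction: Optional[int] = None  # sign(median_b - median_a), exact medians only
    rank_direction: Optional[int] = None  # sign(mean rank b - mean rank a)


def rank_sum_test(
    a: Sequence[CensoredValue | float],
    b: Sequence[CensoredValue | float],
    alpha: float = 0.01,
    *,
    biomarker: str = "",
    label_a: str = "a",
    label_b: str = "b",
    method: str = "auto",
    exact_threshold: int = 25,
    continuity: bool = False,
    compute_medians: bool = True,
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test on the censored ordering.

    ``method`` is "auto" (exact enumeration when n_a + n_b <= exact_threshold
    and the pooled sample is tie-free, tie-corrected normal approximation
    otherwise), "exact", or "asymptotic".  The continuity correction is off by
    default.  Two groups whose values all fall in one tie block (e.g. all
    below-censored at the same bound) are a degenerate comparison and return
    p = 1 with the ``degenerate`` flag set rather than an error.
    """
    a = _as_censored(a)
    b = _as_censored(b)
    if not a or not b:
        raise CohortError("rank_sum_test requires at least one value per group")
    keys = np.concatenate([censored_keys(a), censored_keys(b)])
    med_a = med_b = None
    direction = None
    if compute_medians:
        med_a = _median_or_none(a)
        med_b = _median_or_none(b)
        if med_a is not None and med_b is not None and not med_a.is_censored and not med_b.is_censored:
            direction = int(np.sign(med_b.value - med_a.value))
    u_a, p, used = _u_and_p(keys, len(a), method, exact_threshold, continuity)
    # U counts (a > b) pairs with half-credit for ties, so the sign of
    # U - n_a*n_b/2 is the sign of (mean rank a - mean rank b).
    rank_dir = -int(np.sign(u_a - len(a) * len(b) / 2.0)) if used != "degenerate" else 0
    return ComparisonResult(
        biomarker, label_a, label_b, len(a), len(b),
        p_value=p, significant=bool(p < alpha), degenerate=used == "degenerate",
        method=used,
        median_a=med_a, median_b=med_b, direction=direction, rank_direction=rank_dir,
    )


def censored_keys(values: Sequence[CensoredValue]) -> np.ndarray:
    """(n, 2) array of censored-ordering sort keys (value, censor offset)."""
    return np.array([v.sort_key() for v in values], dtype=float)


def _u_and_p(
    keys: np.ndarray,
    n_a: int,
    method: str = "auto",
    exact_threshold: int = 25,
    continuity: bool = False,
) -> tuple[float, float, str]:
    """U statistic of the first n_a rows and the two-sided p on the censored
    ordering; returns (U_a, p, method used)."""
    n = keys.shape[0]
    n_b = n - n_a
    # tie blocks of the censored ordering (lexicographic in (value, censor))
    order = np.lexsort((keys[:, 1], keys[:, 0]))
    sk = keys[order]
    new_block = np.empty(n, dtype=bool)
    new_block[0] = True
    new_block[1:] = (sk[1:, 0] != sk[:-1, 0]) | (sk[1:, 1] != sk[:-1, 1])
    n_distinct = int(new_block.sum())
    if n_distinct == 1:
        return n_a * n_b / 2.0, 1.0, "degenerate"
    has_ties = n_distinct < n
    if method == "auto":
        use_exact = (not has_ties) and n <= exact_threshold
    elif method in ("exact", "asymptotic"):
        use_exact = method == "exact" and not has_ties
    else:
        raise ValueError(f"unknown method {method!r}")
    if use_exact:
        codes = np.empty(n, dtype=float)
        codes[order] = np.cumsum(new_block) - 1
        res = sps.mannwhitneyu(codes[:n_a], codes[n_a:], alternative="two-sided", method="exact")
        return float(res.statistic), float(min(1.0, res.pvalue)), "exact"
    # midranks per tie block, tie-corrected variance, normal approximation
    starts = np.flatnonzero(new_block)
    counts = np.diff(np.append(starts, n)).astype(float)
    block_midrank = starts + (counts + 1) / 2.0  # 1-based midrank of each block
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.repeat(block_midrank, counts.astype(int))
    u_a = float(ranks[:n_a].sum()) - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0
    tie_term = float((counts**3 - counts).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if var <= 0:
        return u_a, 1.0, "asymptotic"
    numerator = abs(u_a - mu)
    if continuity:
        numerator = max(numerator - 0.5, 0.0)
    z = numerator / math.sqrt(var)
    return u_a, float(min(1.0, 2.0 * sps.norm.sf(z))), "asymptotic"


def _median_or_none(values: Sequence[CensoredValue]) -> Optional[CensoredValue]:
    try:
        return censored_median(values)
    except CohortError:
        return None


def censored_percentile(
    values: Sequence[CensoredValue | float],
    q: float,
    method: str = "linear",
) -> CensoredValue:
    """Quantile of the censored ordering.

    The quantile position is computed from the chosen plotting-position family
    (default: linear interpolation of order statistics).  Interpolation happens
    only when the two bracketing order statistics are both exact; if either is
    censored the censored bound itself is returned, since no number between a
    "<b" and an exact value is defensible.  Two *different* censored values at
    the quantile position (e.g. "<1.71" next to "<2.5") cannot be harmonized
    automatically and raise an error.
    """
    values = _as_censored(values)
    if not values:
        raise CohortError("censored_percentile of empty sequence")
    if not 0.0 < q < 1.0:
        raise CohortError(f"q must be in (0, 1), got {q}")
    try:
        a_const, b_const = QUANTILE_METHODS[method]
    except KeyError:
        raise CohortError(f"unknown quantile method {method!r}; choose from {sorted(QUANTILE_METHODS)}")
    ordered = sorted(values, key=CensoredValue.sort_key)
    n = len(ordered)
    h = q * (n + 1 - a_const - b_const) + a_const - 1  # virtual index, 0-based
    h = min(max(h, 0.0), n - 1.0)
    lo = math.floor(h)
    hi = math.ceil(h)
    g = h - lo
    vlo, vhi = ordered[lo], ordered[hi]
    if lo == hi or vlo == vhi:
        return vlo
    if not vlo.is_censored and not vhi.is_censored:
        return CensoredValue((1 - g) * vlo.value + g * vhi.value)
    if vlo.is_censored and vhi.is_censored:
        raise CohortError(
            f"quantile position falls between two different censored values "
            f"({vlo.render()} and {vhi.render()}); harmonize bounds explicitly"
        )
    return vlo if vlo.is_censored else vhi


def censored_median(values: Sequence[CensoredValue | float], method: str = "linear") -> CensoredValue:
    """Median on the censored ordering; "<bound" when the middle is below-LLOQ."""
    return censored_percentile(values, 0.5, method=method)


@dataclass(frozen=True)
class GroupSummary:
    """Reference-interval style summary of one group x biomarker."""

    biomarker: str
    group: str
    n: int
    median: CensoredValue
    p2_5: CensoredValue
    p97_5: CensoredValue
    range_min: CensoredValue
    range_max: CensoredValue


def summarize_group(
    cohort: Cohort,
    group: str,
    biomarker: str,
    quantile_method: str = "linear",
) -> GroupSummary:
    values = cohort.group_values(group, biomarker)
    if not values:
        raise CohortError(f"group {group!r} has no measurements of {biomarker!r}")
    ordered = sorted(_as_censored(values), key=CensoredValue.sort_key)
    return GroupSummary(
        biomarker=biomarker,
        group=group,
        n=len(ordered),
        median=censored_median(ordered, method=quantile_method),
        p2_5=censored_percentile(ordered, 0.025, method=quantile_method),
        p97_5=censored_percentile(ordered, 0.975, method=quantile_method),
        range_min=ordered[0],
        range_max=ordered[-1],
    )


def format_summary(summary: GroupSummary, percentile_threshold: int = 20) -> dict[str, str]:
    """Render a summary the way clinical reference tables print them:
    percentiles for groups with n >= threshold, plain range otherwise."""
    if summary.n >= percentile_threshold:
        spread = f"{summary.p2_5.render()}–{summary.p97_5.render()}"
    else:
        spread = f"{summary.range_min.render()}–{summary.range_max.render()}"
    return {"median": summary.median.render(), "spread": spread}


def table1(cohort: Cohort, percentile_threshold: int = 20, quantile_method: str = "linear"):
    """Summary table over all groups x biomarkers (pandas DataFrame of strings).

    Cells where a biomarker was not determined in a group read "n. a.".
    """
    import pandas as pd

    groups = sorted(cohort.groups)
    rows = {}
    for marker in cohort.biomarker_names:
        row = {}
        for g in groups:
            try:
                s = summarize_group(cohort, g, marker, quantile_method=quantile_method)
            except CohortError:
                row[(g, "median")] = "n. a."
                row[(g, "spread")] = ""
                continue
            rendered = format_summary(s, percentile_threshold)
            row[(g, "median")] = rendered["median"]
            row[(g, "spread")] = rendered["spread"]
        rows[marker] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    return frame.sort_index()


def adjust_pvalues(pvalues: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Optional multiple-testing adjustment (off by default everywhere)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(list(pvalues), method=method)[1]
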