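"""Subsampling divergence analysis: compare p-value distributions between
group pairs to separate environmental from species signal.

For a pair of groups, repeatedly draw k individuals from each (default k=8,
without replacement within a draw), run the censoring-aware rank-sum test per
biomarker, and pool the resulting p-values into one distribution per pair.
A pair of groups whose distribution sits lower (more small p-values) is more
divergent.  Comparing the distributions of wild-wild, wild-captive and
captive-captive pairs of bonobos and chimpanzees quantifies how much of the
between-group signal the environment contributes: if environment dominates,
the wild-wild cross-species pair is the least divergent.

Exhaustive enumeration of all k-subsets is combinatorially infeasible
(C(50,8) is ~5.4e8), so draws are seeded random subsamples; the draw count is
part of the design and the whole procedure is bit-reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CensoredValue, Cohort, CohortError
from .stats import ComparisonResult, rank_sum_test

__all__ = [
    "SubsampleDesign",
    "PValueDistribution",
    "subsample_pvalues",
    "compare_divergence",
    "divergence_analysis",
    "DEFAULT_PAIRS",
]

log = logging.getLogger("seroclade")

#: The four bonobo x chimpanzee group pairs of the published analysis:
#: wild-wild, the two cross-environment pairs, and captive-captive.
DEFAULT_PAIRS = (
    ("B-CD", "Ch-SL"),
    ("B-CD", "Ch-DE"),
    ("B-DE", "Ch-SL"),
    ("B-DE", "Ch-DE"),
)


@dataclass(frozen=True)
class SubsampleDesign:
    group_a: str
    group_b: str
    k: int = 8
    n_draws: int = 1000
    seed: int = 0
    biomarkers: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.k < 1 or self.n_draws < 1:
            raise CohortError("k and n_draws must be >= 1")


@dataclass
class PValueDistribution:
    """Pooled p-values from all draws x biomarkers, with provenance."""

    design: SubsampleDesign
    table: pd.DataFrame  # draw, biomarker, p_value, degenerate

    @property
    def values(self) -> np.ndarray:
        return self.table["p_value"].to_numpy()

    def median_p(self) -> float:
        return float(np.median(self.values))

    def n_degenerate(self) -> int:
        return int(self.table["degenerate"].sum())


def _draw_pool(cohort: Cohort, label: str, markers: Sequence[str]) -> list[str]:
    """Subjects of a group with at least one measurement among ``markers``."""
    ids = []
    for s in cohort.subjects_in(label=label):
        if any((s.subject_id, m) in cohort.measurements for m in markers):
            ids.append(s.subject_id)
    return sorted(ids)


def subsample_pvalues(cohort: Cohort, design: SubsampleDesign, **test_kwargs) -> PValueDistribution:
    """Run the subsampled rank-sum comparisons for one group pair.

    Each draw samples ``k`` subjects without replacement from each group
    (self-comparisons of a group against itself are allowed and draw two
    independent subsets).  Tests that are degenerate (all values in one tie
    block) record p = 1 with a flag; biomarkers where a draw yields an empty
    side are skipped and logged.
    """
    markers = list(design.biomarkers) if design.biomarkers else cohort.biomarker_names
    pool_a = _draw_pool(cohort, design.group_a, markers)
    pool_b = _draw_pool(cohort, design.group_b, markers)
    for label, pool in ((design.group_a, pool_a), (design.group_b, pool_b)):
        if design.k > len(pool):
            raise CohortError(
                f"subsample size k={design.k} exceeds the {len(pool)} eligible subjects of group {label!r}"
            )
    rng = np.random.default_rng(design.seed)
    records = []
    n_skipped = 0
    for draw in range(design.n_draws):
        ids_a = [pool_a[i] for i in rng.choice(len(pool_a), size=design.k, replace=False)]
        ids_b = [pool_b[i] for i in rng.choice(len(pool_b), size=design.k, replace=False)]
        for marker in markers:
            va = cohort.values(ids_a, marker)
            vb = cohort.values(ids_b, marker)
            if not va or not vb:
                n_skipped += 1
                continue
            res = rank_sum_test(va, vb, biomarker=marker, compute_medians=False, **test_kwargs)
            records.append(
                {"draw": draw, "biomarker": marker, "p_value": res.p_value, "degenerate": res.degenerate}
            )
    if n_skipped:
        log.info(
            "subsample_pvalues(%s vs %s): skipped %d draw x biomarker tests with an empty side",
            design.group_a, design.group_b, n_skipped,
        )
    return PValueDistribution(design=design, table=pd.DataFrame.from_records(records))


def compare_divergence(dist_x: PValueDistribution, dist_y: PValueDistribution) -> ComparisonResult:
    """Two-sided rank-sum test between two pooled p-value distributions.

    ``rank_direction`` < 0 means distribution y has the smaller p-values,
    i.e. pair y is the more divergent one.
    """
    px = [CensoredValue(float(p)) for p in dist_x.values]
    py = [CensoredValue(float(p)) for p in dist_y.values]
    return rank_sum_test(
        px, py,
        label_a=f"{dist_x.design.group_a}|{dist_x.design.group_b}",
        label_b=f"{dist_y.design.group_a}|{dist_y.design.group_b}",
        biomarker="pvalue_distribution",
    )


def divergence_analysis(
    cohort: Cohort,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    *,
    k: int = 8,
    n_draws: int = 1000,
    seed: int = 0,
    biomarkers: Optional[Sequence[str]] = None,
    **test_kwargs,
) -> dict:
    """Subsample every pair and cross-compare all p-value distributions.

    Returns {"distributions": {pair: PValueDistribution},
    "comparisons": DataFrame of all pairwise compare_divergence results,
    "median_p": {pair: median pooled p}} — the least divergent pair is the
    one with the highest median p.  Each pair gets an independent seed stream
    derived from ``seed`` and its position.
    """
    markers = tuple(biomarkers) if biomarkers else None
    dists: dict[tuple[str, str], PValueDistribution] = {}
    for i, (ga, gb) in enumerate(pairs):
        design = SubsampleDesign(ga, gb, k=k, n_draws=n_draws, seed=seed * 7919 + i, biomarkers=markers)
        dists[(ga, gb)] = subsample_pvalues(cohort, design, **test_kwargs)
    rows = []
    keys = list(dists)
    for i, kx in enumerate(keys):
        for ky in keys[i + 1:]:
            res = compare_divergence(dists[kx], dists[ky])
            rows.append(
                {
                    "pair_x": "|".join(kx),
                    "pair_y": "|".join(ky),
                    "p_value": res.p_value,
                    "more_divergent": ("|".join(ky) if res.rank_direction is not None and res.rank_direction < 0
                                       else "|".join(kx) if res.rank_direction else "tie"),
                }
            )
    return {
        "distributions": dists,
        "comparisons": pd.DataFrame.from_records(rows),
        "median_p": {"|".join(k_): d.median_p() for k_, d in dists.items()},
    }
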