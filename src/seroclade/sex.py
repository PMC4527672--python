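"""Male-vs-female biomarker comparisons within each (species, environment) group.

Sex-specific physiology can masquerade as a species difference when sex
ratios differ between groups, so each group is screened separately: a
censoring-aware rank-sum test per biomarker, plus the per-group percentage of
biomarkers that differ between the sexes.  Wild-born and captive-born
conspecifics are never mixed in a sex test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort
from .stats import rank_sum_test

__all__ = ["SexDifferenceTable", "sex_differences"]

log = logging.getLogger("seroclade")

_DIR = {1: "higher_in_female", -1: "higher_in_male", 0: "ns", None: "ns"}


@dataclass
class SexDifferenceTable:
    """Per-(group, biomarker) test results and per-group summary percentages."""

    per_test: pd.DataFrame   # group, biomarker, n_male, n_female, p_value, significant, direction
    per_group: pd.DataFrame  # indexed by group: n_tested, n_significant, percent
    alpha: float
    denominator: str

    def percent(self, group: str) -> float:
        return float(self.per_group.loc[group, "percent"])


def sex_differences(
    cohort: Cohort,
    alpha: float = 0.01,
    *,
    denominator: str = "testable",
    **test_kwargs,
) -> SexDifferenceTable:
    """Screen every group for sex differences in every biomarker.

    ``denominator`` sets the base of the per-group percentage: "testable"
    (markers with both sexes measured in that group, the default) or "total"
    (all biomarkers registered in the cohort).  Groups with only one sex are
    excluded with a warning.
    """
    if denominator not in ("testable", "total"):
        raise ValueError(f"denominator must be 'testable' or 'total', got {denominator!r}")
    records = []
    group_rows = {}
    for label in sorted(cohort.groups):
        males = cohort.subjects_in(label=label, sex="male")
        females = cohort.subjects_in(label=label, sex="female")
        if not cohort.subjects_in(label=label):
            continue
        if not males or not females:
            log.warning("group %s has a single sex; excluded from the sex screen", label)
            continue
        n_tested = 0
        n_significant = 0
        for marker in cohort.biomarker_names:
            vm = cohort.values(males, marker)
            vf = cohort.values(females, marker)
            if not vm or not vf:
                continue
            res = rank_sum_test(
                vm, vf, alpha,
                biomarker=marker, label_a=f"{label}:male", label_b=f"{label}:female",
                compute_medians=False, **test_kwargs,
            )
            n_tested += 1
            n_significant += int(res.significant)
            records.append(
                {
                    "group": label,
                    "biomarker": marker,
                    "n_male": res.n_a,
                    "n_female": res.n_b,
                    "p_value": res.p_value,
                    "significant": res.significant,
                    "direction": _DIR[res.rank_direction] if res.significant else "ns",
                }
            )
        base = n_tested if denominator == "testable" else len(cohort.biomarkers)
        group_rows[label] = {
            "n_tested": n_tested,
            "n_significant": n_significant,
            "percent": 100.0 * n_significant / base if base else 0.0,
        }
    per_test = pd.DataFrame.from_records(records)
    per_group = pd.DataFrame.from_dict(group_rows, orient="index")
    return SexDifferenceTable(per_test=per_test, per_group=per_group, alpha=alpha, denominator=denominator)
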