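"""Wild-born vs captive-born screens within species, and their intersection
with lineage-specific calls.

Biomarkers that differ between conspecifics raised in different environments
are plausibly driven by short-term environmental factors (diet, activity,
husbandry) rather than genetics; intersecting the flag set with the
lineage-specific calls isolates the environment-robust lineage changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cohort import Cohort, CohortError
from .lineage import LineageAssignment
from .stats import rank_sum_test

__all__ = ["EnvironmentFlags", "RobustLineageReport", "environment_flags", "robust_lineage_set"]

log = logging.getLogger("seroclade")

_DIR = {1: "higher_in_captive", -1: "higher_in_wild", 0: "ns", None: "ns"}


@dataclass
class EnvironmentFlags:
    """Per-biomarker wild-vs-captive outcome for bonobos and chimpanzees.

    ``table`` is indexed by biomarker with per-species p-values, directions,
    and tested/flagged booleans; ``chimp_scope`` records which chimpanzee
    pooling produced the chimp column.
    """

    table: pd.DataFrame
    alpha: float
    chimp_scope: str

    def summary(self) -> dict:
        t = self.table
        return {
            "tested": int(t["tested"].sum()),
            "flagged_bonobo": int((t["p_bonobo"] < self.alpha).sum()),
            "flagged_chimpanzee": int((t["p_chimpanzee"] < self.alpha).sum()),
            "flagged_union": int(t["flagged"].sum()),
            "tested_not_flagged": int((t["tested"] & ~t["flagged"]).sum()),
        }

    def flagged_markers(self) -> list[str]:
        return sorted(self.table.index[self.table["flagged"]])

    def offending_species(self, biomarker: str) -> list[str]:
        row = self.table.loc[biomarker]
        out = []
        if row["p_bonobo"] == row["p_bonobo"] and row["p_bonobo"] < self.alpha:  # NaN-safe
            out.append("bonobo")
        if row["p_chimpanzee"] == row["p_chimpanzee"] and row["p_chimpanzee"] < self.alpha:
            out.append("chimpanzee")
        return out


def _species_env_values(cohort: Cohort, species: Sequence[str], environment: str, biomarker: str):
    return cohort.values(
        [s for sp in species for s in cohort.subjects_in(species=sp, environment=environment)],
        biomarker,
    )


def environment_flags(
    cohort: Cohort,
    alpha: float = 0.01,
    *,
    chimp_scope: str = "matched",
    **test_kwargs,
) -> EnvironmentFlags:
    """Rank-sum test wild vs captive conspecifics, per biomarker per species.

    Bonobos compare wild-born vs captive-born bonobos.  For chimpanzees the
    captive animals are West African, so ``chimp_scope="matched"`` (default)
    compares wild West African vs captive West African chimpanzees;
    ``"pooled_wild"`` pools all wild chimpanzees instead.  A biomarker absent
    from either environment of a species is untested for that species;
    untested in both species means untested overall and never flagged.
    """
    if chimp_scope not in ("matched", "pooled_wild"):
        raise CohortError(f"chimp_scope must be 'matched' or 'pooled_wild', got {chimp_scope!r}")
    chimp_wild_species = ["chimp_west"] if chimp_scope == "matched" else ["chimp_west", "chimp_central"]
    pairs = {
        "bonobo": (["bonobo"], ["bonobo"]),
        "chimpanzee": (chimp_wild_species, ["chimp_west"]),
    }
    rows = {}
    for marker in cohort.biomarker_names:
        row: dict[str, object] = {}
        for species, (wild_sp, captive_sp) in pairs.items():
            wild = _species_env_values(cohort, wild_sp, "wild_born", marker)
            captive = _species_env_values(cohort, captive_sp, "captive_born", marker)
            if not wild or not captive:
                row[f"p_{species}"] = float("nan")
                row[f"dir_{species}"] = "untested"
                row[f"tested_{species}"] = False
                continue
            res = rank_sum_test(
                wild, captive, alpha,
                biomarker=marker, label_a=f"{species}:wild_born", label_b=f"{species}:captive_born",
                compute_medians=False, **test_kwargs,
            )
            row[f"p_{species}"] = res.p_value
            row[f"dir_{species}"] = _DIR[res.rank_direction] if res.significant else "ns"
            row[f"tested_{species}"] = True
        row["tested"] = bool(row["tested_bonobo"] or row["tested_chimpanzee"])
        row["flagged"] = bool(
            (row["tested_bonobo"] and row["p_bonobo"] < alpha)
            or (row["tested_chimpanzee"] and row["p_chimpanzee"] < alpha)
        )
        rows[marker] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    for species in ("bonobo", "chimpanzee"):
        if not table.empty and not table[f"tested_{species}"].any():
            log.warning("no wild/captive contrast available for %s; column untested", species)
    return EnvironmentFlags(table=table, alpha=alpha, chimp_scope=chimp_scope)


@dataclass
class RobustLineageReport:
    """Lineage-specific markers split by environmental robustness."""

    robust: list[str]
    excluded: list[tuple[str, list[str]]]  # (biomarker, offending species)

    def __iter__(self):
        return iter(self.robust)


def robust_lineage_set(
    assignments: Sequence[LineageAssignment],
    flags: EnvironmentFlags,
) -> RobustLineageReport:
    """Lineage-specific biomarkers with no wild/captive difference.

    Returns both the surviving set and the complementary report of
    lineage-specific markers removed by the environment screen, with the
    species driving each removal.
    """
    robust: list[str] = []
    excluded: list[tuple[str, list[str]]] = []
    for a in assignments:
        if a.category == "non_specific":
            continue
        if a.biomarker in flags.table.index and bool(flags.table.loc[a.biomarker, "flagged"]):
            excluded.append((a.biomarker, flags.offending_species(a.biomarker)))
        else:
            robust.append(a.biomarker)
    return RobustLineageReport(robust=sorted(robust), excluded=sorted(excluded))
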