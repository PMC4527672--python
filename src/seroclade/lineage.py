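"""Outgroup-rooted lineage-specific assignment of biomarker level changes.

Each biomarker is sorted into one of seven categories — specific to humans,
great apes, bonobos, chimpanzees, Central African chimpanzees, West African
chimpanzees, or non-lineage-specific — by a cascade of rank-sum tests
polarized with an outgroup (rhesus macaques).  A change is specific to
lineage L when

  (i)   pooled L differs from the pooled rest of the ingroup,
  (ii)  the rest of the ingroup is internally homogeneous (no significant
        difference between its member taxa),
  (iii) L differs from the outgroup, and
  (iv)  L differs from each member taxon of the rest individually,

all at the same significance threshold (default p < 0.01), with environments
pooled within species.  No outgroup-specific category exists: polarizing a
change on the outgroup branch would need a second, more distant outgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .cohort import CensoredValue, Cohort, CohortError
from .stats import ComparisonResult, censored_keys, rank_sum_test
from .stats import _u_and_p  # internal fast path shared within the package

__all__ = [
    "SpeciesTree",
    "LineageAssignment",
    "ClassificationReport",
    "LineageError",
    "assign_lineage",
    "classify_all",
]

CATEGORIES = (
    "human",
    "great_ape",
    "bonobo",
    "chimpanzee",
    "chimp_central",
    "chimp_west",
    "non_specific",
)


class LineageError(CohortError):
    pass


@dataclass(frozen=True)
class SpeciesTree:
    """Rooted ingroup topology plus designated outgroup.

    ``clades`` names internal nodes as frozensets of leaves; ``candidates``
    lists the lineages eligible for a specific call, leaf-first so that ties
    between nested lineages break deterministically toward the tips.
    ``pooling`` maps each leaf to its species-level unit (subspecies pooled),
    used when complement taxa are compared at species scope.
    """

    leaves: tuple[str, ...]
    outgroup: str
    clades: Mapping[str, frozenset[str]]
    candidates: tuple[str, ...]
    pooling: Mapping[str, str]

    @classmethod
    def default(cls) -> "SpeciesTree":
        """The primate cladogram ((human,(bonobo,(chimp_central,chimp_west))),rhesus)."""
        clades = {
            "chimpanzee": frozenset({"chimp_central", "chimp_west"}),
            "great_ape": frozenset({"bonobo", "chimp_central", "chimp_west"}),
        }
        return cls(
            leaves=("human", "bonobo", "chimp_central", "chimp_west"),
            outgroup="rhesus",
            clades=clades,
            candidates=("human", "bonobo", "chimp_central", "chimp_west", "chimpanzee", "great_ape"),
            pooling={
                "human": "human",
                "bonobo": "bonobo",
                "chimp_central": "chimpanzee",
                "chimp_west": "chimpanzee",
            },
        )

    @classmethod
    def from_newick(cls, newick: str, outgroup: str) -> "SpeciesTree":
        """Build from a newick string with named internal nodes.

        The outgroup must be a leaf of the tree; every named internal node of
        the ingroup becomes a candidate clade.  Species-level pooling defaults
        to the identity (every leaf is its own unit).
        """
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        labels = [t.label for t in tree.taxon_namespace]
        if outgroup not in labels:
            raise LineageError(f"outgroup {outgroup!r} is not a leaf of the tree ({labels})")
        leaves = tuple(l for l in labels if l != outgroup)
        clades: dict[str, frozenset[str]] = {}
        for node in tree.preorder_internal_node_iter():
            if node.label is None:
                continue
            members = frozenset(t.taxon.label for t in node.leaf_iter())
            if outgroup in members:
                continue
            if len(members) < len(leaves):  # proper sub-clade of the ingroup
                clades[node.label] = members
        candidates = leaves + tuple(sorted(clades, key=lambda c: len(clades[c])))
        return cls(
            leaves=leaves,
            outgroup=outgroup,
            clades=clades,
            candidates=candidates,
            pooling={l: l for l in leaves},
        )

    def species_of(self, lineage: str) -> frozenset[str]:
        if lineage in self.leaves:
            return frozenset({lineage})
        if lineage in self.clades:
            return self.clades[lineage]
        raise LineageError(f"unknown lineage {lineage!r}")

    def complement_units(self, lineage: str, scope: str = "species") -> dict[str, frozenset[str]]:
        """Partition the ingroup complement of ``lineage`` into taxa to test.

        scope="species" pools subspecies into their species-level unit
        (restricted to complement members); scope="subspecies" keeps leaves.
        """
        if scope not in ("species", "subspecies"):
            raise LineageError(f"scope must be 'species' or 'subspecies', got {scope!r}")
        complement = frozenset(self.leaves) - self.species_of(lineage)
        units: dict[str, set[str]] = {}
        for leaf in self.leaves:
            if leaf not in complement:
                continue
            name = self.pooling.get(leaf, leaf) if scope == "species" else leaf
            units.setdefault(name, set()).add(leaf)
        # a pooled unit reduced to a single leaf keeps the leaf's name
        out: dict[str, frozenset[str]] = {}
        for name, members in units.items():
            if len(members) == 1:
                (only,) = members
                out[only] = frozenset(members)
            else:
                out[name] = frozenset(members)
        return out


@dataclass(frozen=True)
class RuleStep:
    condition: str
    p_value: Optional[float]
    passed: bool


@dataclass
class LineageAssignment:
    biomarker: str
    category: str
    trace: list[RuleStep] = field(default_factory=list)
    comparisons: list[ComparisonResult] = field(default_factory=list)
    passing: list[str] = field(default_factory=list)
    ambiguous: bool = False


def _values_by_species(cohort: Cohort, biomarker: str, tree: SpeciesTree) -> dict[str, list[CensoredValue]]:
    needed = list(tree.leaves) + [tree.outgroup]
    out = {}
    for sp in needed:
        vals = cohort.species_values(sp, biomarker)
        if not vals:
            raise LineageError(f"species {sp!r} has no measurements of biomarker {biomarker!r}")
        out[sp] = vals
    return out


def assign_lineage(
    cohort: Cohort,
    biomarker: str,
    tree: SpeciesTree | None = None,
    alpha: float = 0.01,
    *,
    scope: str = "species",
    full_polarity: bool = False,
    strict_environment: bool = False,
    **test_kwargs,
) -> LineageAssignment:
    """Run the classification cascade for one biomarker.

    ``scope`` controls whether complement taxa are compared at species level
    (chimpanzee subspecies pooled, the default) or subspecies-resolved.
    ``full_polarity`` additionally requires the ingroup complement NOT to
    differ from the outgroup.  ``strict_environment`` additionally requires
    significance against every (species, environment) stratum of the
    complement.  Candidates are evaluated in tree order; if more than one
    passes, the assignment is flagged ambiguous and resolved to the first.
    """
    tree = tree or SpeciesTree.default()
    if biomarker not in cohort.biomarkers:
        raise LineageError(f"biomarker {biomarker!r} is not registered in the cohort")
    by_species = _values_by_species(cohort, biomarker, tree)

    keys_by_species = {sp: censored_keys(vals) for sp, vals in by_species.items()}
    tkw = {
        "method": test_kwargs.get("method", "auto"),
        "exact_threshold": test_kwargs.get("exact_threshold", 25),
        "continuity": test_kwargs.get("continuity", False),
    }
    unknown = set(test_kwargs) - set(tkw)
    if unknown:
        raise TypeError(f"unexpected test options {sorted(unknown)}")
    pool_cache: dict[frozenset[str], np.ndarray] = {}

    def pooled(species: Iterable[str]) -> np.ndarray:
        key = frozenset(species)
        if key not in pool_cache:
            pool_cache[key] = np.concatenate([keys_by_species[sp] for sp in sorted(key)])
        return pool_cache[key]

    cache: dict[tuple[frozenset[str], frozenset[str]], ComparisonResult] = {}

    def test(sa: frozenset[str], sb: frozenset[str], la: str, lb: str) -> ComparisonResult:
        key = (sa, sb) if tuple(sorted(sa)) <= tuple(sorted(sb)) else (sb, sa)
        if key not in cache:
            ka, kb = pooled(key[0]), pooled(key[1])
            u_a, p, used = _u_and_p(np.concatenate([ka, kb]), ka.shape[0], **tkw)
            cache[key] = ComparisonResult(
                biomarker=biomarker,
                label_a="+".join(sorted(key[0])), label_b="+".join(sorted(key[1])),
                n_a=ka.shape[0], n_b=kb.shape[0],
                p_value=p, significant=bool(p < alpha), degenerate=used == "degenerate",
                method=used,
                rank_direction=(-int(np.sign(u_a - ka.shape[0] * kb.shape[0] / 2.0))
                                if used != "degenerate" else 0),
            )
        return cache[key]

    assignment = LineageAssignment(biomarker=biomarker, category="non_specific")
    outgroup = frozenset({tree.outgroup})

    for lineage in tree.candidates:
        lineage_sp = tree.species_of(lineage)
        complement = frozenset(tree.leaves) - lineage_sp
        units = tree.complement_units(lineage, scope=scope)
        steps: list[RuleStep] = []
        ok = True

        def record(condition: str, result: ComparisonResult, want_significant: bool) -> None:
            nonlocal ok
            passed = result.significant if want_significant else not result.significant
            steps.append(RuleStep(condition, result.p_value, passed))
            assignment.comparisons.append(result)
            ok = ok and passed

        record(f"{lineage} vs pooled complement", test(lineage_sp, complement, lineage, "complement"), True)
        for name_a in sorted(units):
            for name_b in sorted(units):
                if name_a >= name_b:
                    continue
                record(
                    f"complement homogeneity: {name_a} vs {name_b}",
                    test(units[name_a], units[name_b], name_a, name_b),
                    False,
                )
        record(f"{lineage} vs outgroup {tree.outgroup}", test(lineage_sp, outgroup, lineage, tree.outgroup), True)
        for name in sorted(units):
            record(f"{lineage} vs {name}", test(lineage_sp, units[name], lineage, name), True)
        if full_polarity and complement:
            record(
                f"polarity: complement vs outgroup {tree.outgroup}",
                test(complement, outgroup, "complement", tree.outgroup),
                False,
            )
        if strict_environment:
            strata: dict[tuple[str, str], list[CensoredValue]] = {}
            for s in cohort.subjects_in(species=complement):
                v = cohort.measurements.get((s.subject_id, biomarker))
                if v is not None:
                    strata.setdefault((s.species, s.environment), []).append(v)
            for (sp, env), vals in sorted(strata.items()):
                ka = pooled(lineage_sp)
                kb = censored_keys(vals)
                u_a, p, used = _u_and_p(np.concatenate([ka, kb]), ka.shape[0], **tkw)
                res = ComparisonResult(
                    biomarker=biomarker, label_a=lineage, label_b=f"{sp}:{env}",
                    n_a=ka.shape[0], n_b=kb.shape[0],
                    p_value=p, significant=bool(p < alpha),
                    degenerate=used == "degenerate", method=used,
                )
                assignment.comparisons.append(res)
                steps.append(RuleStep(f"{lineage} vs stratum {sp}:{env}", res.p_value, res.significant))
                ok = ok and res.significant

        assignment.trace.extend(steps)
        if ok:
            assignment.passing.append(lineage)

    if assignment.passing:
        assignment.category = assignment.passing[0]
        assignment.ambiguous = len(assignment.passing) > 1
    return assignment


@dataclass
class ClassificationReport:
    assignments: list[LineageAssignment]
    not_classifiable: list[tuple[str, str]]  # (biomarker, reason)
    counts: dict[str, int]

    def category_of(self, biomarker: str) -> Optional[str]:
        for a in self.assignments:
            if a.biomarker == biomarker:
                return a.category
        return None


def classify_all(
    cohort: Cohort,
    tree: SpeciesTree | None = None,
    alpha: float = 0.01,
    **kwargs,
) -> ClassificationReport:
    """Classify every biomarker measured in all species of the tree.

    Biomarkers lacking measurements in at least one species (e.g. not
    determined in a group) are reported as not classifiable — a distinct
    outcome from non-specific, which is a verdict of the cascade.
    """
    tree = tree or SpeciesTree.default()
    assignments: list[LineageAssignment] = []
    not_classifiable: list[tuple[str, str]] = []
    for marker in cohort.biomarker_names:
        try:
            assignments.append(assign_lineage(cohort, marker, tree, alpha, **kwargs))
        except LineageError as exc:
            not_classifiable.append((marker, str(exc)))
    counts = {c: 0 for c in CATEGORIES}
    for a in assignments:
        counts[a.category] = counts.get(a.category, 0) + 1
    return ClassificationReport(assignments, not_classifiable, counts)
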