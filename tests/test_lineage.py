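import math

import pytest

from conftest import monotone_square, single_marker_config
from seroclade import (
    CensoredValue,
    EffectSpec,
    LineageError,
    SpeciesTree,
    assign_lineage,
    classify_all,
    generate_cohort,
)
from seroclade.lineage import CATEGORIES


class TestSpeciesTree:
    def test_default_topology(self):
        t = SpeciesTree.default()
        assert t.outgroup == "rhesus"
        assert t.species_of("great_ape") == {"bonobo", "chimp_central", "chimp_west"}
        assert t.species_of("chimpanzee") == {"chimp_central", "chimp_west"}
        assert t.candidates[0] == "human"  # leaf-first deterministic order

    def test_complement_units_species_scope(self):
        t = SpeciesTree.default()
        assert set(t.complement_units("human")) == {"bonobo", "chimpanzee"}
        assert set(t.complement_units("bonobo")) == {"human", "chimpanzee"}
        # the remaining chimp subspecies stands alone under species pooling
        assert set(t.complement_units("chimp_central")) == {"human", "bonobo", "chimp_west"}
        assert set(t.complement_units("great_ape")) == {"human"}

    def test_complement_units_subspecies_scope(self):
        t = SpeciesTree.default()
        assert set(t.complement_units("human", scope="subspecies")) == {
            "bonobo", "chimp_central", "chimp_west",
        }

    def test_from_newick(self):
        t = SpeciesTree.from_newick(
            "((human,(bonobo,(chimp_central,chimp_west)chimpanzee)great_ape),rhesus);",
            outgroup="rhesus",
        )
        assert set(t.leaves) == {"human", "bonobo", "chimp_central", "chimp_west"}
        assert t.clades["chimpanzee"] == {"chimp_central", "chimp_west"}
        assert t.clades["great_ape"] == {"bonobo", "chimp_central", "chimp_west"}
        assert "rhesus" not in t.leaves

    def test_from_newick_bad_outgroup(self):
        with pytest.raises(LineageError):
            SpeciesTree.from_newick("((a,b),c);", outgroup="zz")


def planted(species_shifts, seed, name="m", **kw):
    spec = EffectSpec(name=name, log_baseline=math.log(3.0), species_shift=species_shifts,
                      sigma=0.5, **kw)
    return generate_cohort(single_marker_config(spec, seed=seed))


class TestAssignLineage:
    def test_planted_human_shift_recovered(self):
        cohort = planted({"human": 1.0}, seed=5)
        a = assign_lineage(cohort, "m")
        assert a.category == "human"
        assert not a.ambiguous
        assert a.passing == ["human"]

    def test_planted_bonobo_shift_recovered(self):
        cohort = planted({"bonobo": 1.0}, seed=5)
        assert assign_lineage(cohort, "m").category == "bonobo"

    def test_planted_subspecies_shift(self):
        cohort = planted({"chimp_west": 1.2}, seed=5)
        assert assign_lineage(cohort, "m").category == "chimp_west"

    def test_null_is_non_specific(self):
        cohort = planted({}, seed=5)
        a = assign_lineage(cohort, "m")
        assert a.category == "non_specific"
        assert a.passing == []

    def test_polarity_whole_ingroup_shift_never_a_leaf_call(self):
        """A shift shared by every ingroup species relative to the outgroup
        must resolve to the deepest clade or nothing, never a single tip."""
        for seed in range(5):
            shifts = {sp: 1.5 for sp in ("human", "bonobo", "chimp_central", "chimp_west")}
            cohort = planted(shifts, seed=seed)
            cat = assign_lineage(cohort, "m").category
            assert cat in ("great_ape", "non_specific")

    def test_great_ape_shift_recovered(self):
        shifts = {sp: 1.2 for sp in ("bonobo", "chimp_central", "chimp_west")}
        cohort = planted(shifts, seed=5)
        assert assign_lineage(cohort, "m").category == "great_ape"

    def test_determinism(self):
        cohort = planted({"human": 1.0}, seed=9)
        a1 = assign_lineage(cohort, "m")
        a2 = assign_lineage(cohort, "m")
        assert a1.category == a2.category
        assert [(s.condition, s.p_value, s.passed) for s in a1.trace] == [
            (s.condition, s.p_value, s.passed) for s in a2.trace
        ]

    def test_monotone_transform_invariance(self):
        cohort = planted({"human": 1.0}, seed=13, lloq=2.0)
        transformed = monotone_square(cohort)
        a1 = assign_lineage(cohort, "m")
        a2 = assign_lineage(transformed, "m")
        assert a1.category == a2.category
        assert [s.p_value for s in a1.trace] == pytest.approx(
            [s.p_value for s in a2.trace], abs=1e-12
        )

    def test_missing_species_is_error_naming_species(self, tiny_cohort):
        # cholesterol is measured only in humans and wild bonobos here
        with pytest.raises(LineageError, match="chimp_central.*cholesterol"):
            assign_lineage(tiny_cohort, "cholesterol")

    def test_unknown_biomarker(self, tiny_cohort):
        with pytest.raises(LineageError, match="not registered"):
            assign_lineage(tiny_cohort, "nope")

    def test_rule_trace_records_conditions(self):
        cohort = planted({"human": 1.0}, seed=5)
        a = assign_lineage(cohort, "m")
        conditions = [s.condition for s in a.trace]
        assert "human vs pooled complement" in conditions
        assert "complement homogeneity: bonobo vs chimpanzee" in conditions
        assert "human vs outgroup rhesus" in conditions
        assert "human vs bonobo" in conditions and "human vs chimpanzee" in conditions
        # a passing category requires every condition of its block to pass;
        # the human candidate is evaluated first, so its block heads the trace
        human_block = a.trace[:5]
        assert {s.condition for s in human_block} == {
            "human vs pooled complement",
            "complement homogeneity: bonobo vs chimpanzee",
            "human vs outgroup rhesus",
            "human vs bonobo",
            "human vs chimpanzee",
        }
        assert all(s.passed for s in human_block)


class TestClassifyAll:
    def test_null_panel_mostly_non_specific(self, null_cohort):
        report = classify_all(null_cohort)
        assert report.counts["non_specific"] >= 19  # 20 null markers, alpha=0.01
        assert sum(report.counts.values()) == len(report.assignments) == 20

    def test_mutual_exclusivity_and_completeness(self, human_shift_cohort):
        report = classify_all(human_shift_cohort)
        for a in report.assignments:
            assert a.category in CATEGORIES
        assert sum(report.counts.values()) == len(report.assignments)

    def test_marker_missing_in_one_species_not_classifiable(self, human_shift_cohort):
        import copy

        cohort = copy.deepcopy(human_shift_cohort)
        # emulate "not analyzed" in rhesus for one marker
        for s in cohort.subjects_in(species="rhesus"):
            cohort.measurements.pop((s.subject_id, "marker_00"), None)
        report = classify_all(cohort)
        assert ("marker_00", ) == tuple(m for m, _ in report.not_classifiable)
        reason = dict(report.not_classifiable)["marker_00"]
        assert "rhesus" in reason
        assert len(report.assignments) == 4  # the other markers still classified

    def test_category_lookup(self, human_shift_cohort):
        report = classify_all(human_shift_cohort)
        assert report.category_of("bilirubin_like") == "human"
        assert report.category_of("marker_00") == "non_specific"
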