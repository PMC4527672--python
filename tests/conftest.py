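from __future__ import annotations

import math

import pytest

from seroclade import (
    Censor,
    CensoredValue,
    Cohort,
    EffectSpec,
    ScenarioConfig,
    Subject,
    generate_cohort,
    scenario_library,
)
from seroclade.simulate import DEFAULT_GROUP_SIZES, DEFAULT_SEX_COUNTS

APE_GROUPS = ("B-CD", "B-DE", "Ch-SL", "Ch-DE")


def ape_only_config(effects, seed: int = 0) -> ScenarioConfig:
    """Scenario restricted to the four bonobo/chimp wild-captive groups."""
    return ScenarioConfig(
        effects=tuple(effects),
        group_sizes={g: DEFAULT_GROUP_SIZES[g] for g in APE_GROUPS},
        sex_counts={g: DEFAULT_SEX_COUNTS[g] for g in APE_GROUPS},
        seed=seed,
    )


def single_marker_config(spec: EffectSpec, seed: int = 0) -> ScenarioConfig:
    """Full study-design group sizes, one biomarker."""
    return ScenarioConfig(effects=(spec,), seed=seed)


def monotone_square(cohort: Cohort) -> Cohort:
    """Apply x -> x^2 (strictly increasing on [0, inf)) to every measurement,
    censoring bounds included; used to probe rank invariance."""
    out = Cohort(groups={g.label: (g.species, g.environment) for g in cohort.groups.values()})
    for name, units in cohort.biomarkers.items():
        out.register_biomarker(name, units)
    for s in cohort.subjects.values():
        out.add_subject(s)
    for (sid, marker), v in cohort.measurements.items():
        out.add_measurement(sid, marker, CensoredValue(v.value**2, v.censor))
    return out


@pytest.fixture(scope="session")
def library():
    return scenario_library(seed=0)


@pytest.fixture(scope="session")
def null_cohort(library):
    return generate_cohort(library["null"].with_seed(42))


@pytest.fixture(scope="session")
def human_shift_cohort(library):
    return generate_cohort(library["human_specific_shift"].with_seed(42))


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Hand-built six-subject cohort with exact, censored and missing values."""
    c = Cohort()
    c.register_biomarker("bilirubin", "umol/L")
    c.register_biomarker("cholesterol", "mmol/L")
    subjects = [
        Subject("h1", "human", "captive_born", "male", 30.0, 70.0),
        Subject("h2", "human", "captive_born", "female", 25.0),
        Subject("b1", "bonobo", "wild_born", "male", 6.0, 18.8),
        Subject("b2", "bonobo", "captive_born", "female", 14.0),
        Subject("c1", "chimp_west", "wild_born", "female", 4.0, 27.0),
        Subject("r1", "rhesus", "captive_born", "female", 3.5, 7.2),
    ]
    for s in subjects:
        c.add_subject(s)
    c.add_measurement("h1", "bilirubin", CensoredValue(3.4))
    c.add_measurement("h2", "bilirubin", CensoredValue(1.71, Censor.BELOW))
    c.add_measurement("b1", "bilirubin", CensoredValue(1.71, Censor.BELOW))
    c.add_measurement("b2", "bilirubin", CensoredValue(2.0))
    c.add_measurement("c1", "bilirubin", CensoredValue(1.71, Censor.BELOW))
    c.add_measurement("r1", "bilirubin", CensoredValue(1.71, Censor.BELOW))
    c.add_measurement("h1", "cholesterol", CensoredValue(4.72))
    c.add_measurement("b1", "cholesterol", CensoredValue(5.63))
    # c1, r1, h2, b2: cholesterol missing, not censored
    return c
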