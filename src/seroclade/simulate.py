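"""Synthetic multi-species cohort generator.

Serum clinical-chemistry values are positive and right-skewed, and group
effects (species, sex, wild/captive environment) act roughly multiplicatively,
so values are drawn log-normally:

    value = exp( Normal( log_baseline + species_shift + sex_shift + env_shift,
                         sigma ) )

per subject x biomarker, then censored at the assay's LLOQ/ULOQ — a draw
below the LLOQ is stored as "<lloq", above the ULOQ as ">uloq", exactly as an
analyzer would report it.  Default group sizes and sex ratios follow the
study design this package targets: 20 rhesus macaques (3m/17f), 50 wild and
11 captive bonobos, 121 wild Central African and 76 wild + 19 captive West
African chimpanzees, and 312 humans (156m/156f).  Generation is fully
deterministic given the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .cohort import CensoredValue, Censor, Cohort, CohortError, DEFAULT_GROUPS, Subject

__all__ = [
    "EffectSpec",
    "ScenarioConfig",
    "generate_cohort",
    "scenario_library",
    "save_scenario",
    "load_scenario",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_SEX_COUNTS",
]

#: Study-design group sizes (post-exclusion, as analyzed).
DEFAULT_GROUP_SIZES: Mapping[str, int] = {
    "Rh-DE": 20, "B-CD": 50, "B-DE": 11, "Ch-CG": 121, "Ch-SL": 76, "Ch-DE": 19, "H-DE": 312,
}

#: (males, females) per group.
DEFAULT_SEX_COUNTS: Mapping[str, tuple[int, int]] = {
    "Rh-DE": (3, 17), "B-CD": (28, 22), "B-DE": (7, 4), "Ch-CG": (65, 56),
    "Ch-SL": (34, 42), "Ch-DE": (6, 13), "H-DE": (156, 156),
}

_AGE_RANGES: Mapping[str, tuple[float, float]] = {
    "Rh-DE": (1, 22), "B-CD": (3, 20), "B-DE": (3, 37), "Ch-CG": (2, 42),
    "Ch-SL": (1, 23), "Ch-DE": (8, 46), "H-DE": (18, 65),
}


@dataclass(frozen=True)
class EffectSpec:
    """Log-scale generative model for one biomarker.

    ``log_baseline`` locates the outgroup distribution; per-species,
    per-sex and per-environment shifts are additive on the log scale
    (multiplicative on the measurement scale).  ``env_shift`` applies to
    captive-born individuals of the keyed species.  ``sigma`` is the log-scale
    standard deviation; lloq/uloq are assay bounds in natural units.
    """

    name: str
    log_baseline: float = 0.0
    species_shift: Mapping[str, float] = field(default_factory=dict)
    sex_shift: float = 0.0           # added for females
    env_shift: Mapping[str, float] = field(default_factory=dict)
    sigma: float = 0.5
    lloq: Optional[float] = None
    uloq: Optional[float] = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise CohortError(f"{self.name}: sigma must be > 0, got {self.sigma}")
        if self.lloq is not None and self.uloq is not None and not self.lloq < self.uloq:
            raise CohortError(f"{self.name}: lloq must be < uloq")
        for shift in (*self.species_shift.values(), self.sex_shift, *self.env_shift.values(),
                      self.log_baseline):
            if not math.isfinite(shift):
                raise CohortError(f"{self.name}: shifts must be finite")


@dataclass(frozen=True)
class ScenarioConfig:
    effects: tuple[EffectSpec, ...]
    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    sex_counts: Mapping[str, tuple[int, int]] = field(default_factory=lambda: dict(DEFAULT_SEX_COUNTS))
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.effects:
            raise CohortError("scenario needs at least one biomarker effect spec")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise CohortError(f"group {g!r}: size must be >= 1")
            m, f = self.sex_counts.get(g, (n, 0))
            if m + f != n:
                raise CohortError(f"group {g!r}: sex counts {m}+{f} do not sum to size {n}")

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


def generate_cohort(config: ScenarioConfig) -> Cohort:
    """Draw a full synthetic cohort; bit-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    cohort = Cohort(groups=DEFAULT_GROUPS)
    for spec in config.effects:
        cohort.register_biomarker(spec.name, spec.units)

    for label in sorted(config.group_sizes):
        if label not in cohort.groups:
            raise CohortError(f"group {label!r} not in vocabulary {sorted(cohort.groups)}")
        group = cohort.groups[label]
        n = config.group_sizes[label]
        n_male, n_female = config.sex_counts.get(label, (n, 0))
        sexes = ["male"] * n_male + ["female"] * n_female
        lo_age, hi_age = _AGE_RANGES.get(label, (1.0, 40.0))
        ages = rng.uniform(lo_age, hi_age, size=n)
        weights = rng.lognormal(mean=math.log(40.0), sigma=0.3, size=n)
        subject_ids = [f"{label}-{i:04d}" for i in range(n)]
        for sid, sex, age, w in zip(subject_ids, sexes, ages, weights):
            cohort.add_subject(Subject(sid, group.species, group.environment, sex,
                                       round(float(age), 1), round(float(w), 1)))
        for spec in config.effects:
            mu = (
                spec.log_baseline
                + spec.species_shift.get(group.species, 0.0)
                + spec.env_shift.get(group.species, 0.0) * (group.environment == "captive_born")
            )
            mus = np.full(n, mu) + spec.sex_shift * np.array([s == "female" for s in sexes], dtype=float)
            draws = np.exp(rng.normal(mus, spec.sigma))
            for sid, x in zip(subject_ids, draws):
                if spec.lloq is not None and x < spec.lloq:
                    v = CensoredValue(spec.lloq, Censor.BELOW)
                elif spec.uloq is not None and x > spec.uloq:
                    v = CensoredValue(spec.uloq, Censor.ABOVE)
                else:
                    v = CensoredValue(round(float(x), 6))
                cohort.add_measurement(sid, spec.name, v)
    cohort.validate()
    return cohort


def _null_markers(n: int, prefix: str = "marker") -> list[EffectSpec]:
    # spread baselines so markers look like distinct analytes
    return [
        EffectSpec(name=f"{prefix}_{i:02d}", log_baseline=math.log(5.0) + 0.3 * i, sigma=0.5)
        for i in range(n)
    ]


def scenario_library(seed: int = 0) -> dict[str, ScenarioConfig]:
    """Named scenarios exercising each stage of the pipeline.

    - "null": 20 markers, no group effects anywhere.
    - "human_specific_shift": a bilirubin-like marker — baseline right at the
      LLOQ so the apes are ~85% censored and the outgroup almost fully
      censored, humans shifted up past the bound — plus null markers.
    - "bonobo_specific_shift": one marker elevated in bonobos only.
    - "environment_confounded": a human-shifted marker that also differs
      between wild and captive apes; the cascade calls it human-specific but
      the environment screen must flag and remove it.
    - "environment_only": no species effects, captivity shifts every marker
      (by species-specific amounts), driving the subsampling divergence
      ordering: wild-wild least divergent.

    Effect sizes are fixed constants chosen so the cascade recovers planted
    categories with >= 95% probability at the default group sizes.
    """
    bilirubin_like = EffectSpec(
        name="bilirubin_like",
        log_baseline=0.0,               # median 1.0 at the LLOQ 1.71 => apes mostly censored
        species_shift={"human": 1.22, "rhesus": -0.5},
        sigma=0.5,
        lloq=1.71,
        units="umol/L",
    )
    apoa_like = EffectSpec(
        name="apolipoprotein_a_like",
        log_baseline=math.log(1.6),
        species_shift={"bonobo": 1.0},
        sigma=0.5,
        units="g/L",
    )
    confounded = EffectSpec(
        name="confounded_marker",
        log_baseline=math.log(3.0),
        species_shift={"human": 1.0},
        env_shift={"bonobo": 0.8, "chimp_west": 0.8, "chimp_central": 0.8},
        sigma=0.5,
    )
    env_only = [
        replace(spec, env_shift={"bonobo": 0.8, "chimp_west": 0.5, "chimp_central": 0.5})
        for spec in _null_markers(5, prefix="env_marker")
    ]
    return {
        "null": ScenarioConfig(effects=tuple(_null_markers(20)), seed=seed, name="null"),
        "human_specific_shift": ScenarioConfig(
            effects=(bilirubin_like, *_null_markers(4)), seed=seed, name="human_specific_shift"
        ),
        "bonobo_specific_shift": ScenarioConfig(
            effects=(apoa_like, *_null_markers(4)), seed=seed, name="bonobo_specific_shift"
        ),
        "environment_confounded": ScenarioConfig(
            effects=(confounded, *_null_markers(4)), seed=seed, name="environment_confounded"
        ),
        "environment_only": ScenarioConfig(effects=tuple(env_only), seed=seed, name="environment_only"),
    }


# -- YAML round trip -------------------------------------------------------

def save_scenario(config: ScenarioConfig, path: str | Path) -> Path:
    doc = {
        "name": config.name,
        "seed": config.seed,
        "group_sizes": dict(config.group_sizes),
        "sex_counts": {g: list(mf) for g, mf in config.sex_counts.items()},
        "effects": [
            {
                "name": e.name,
                "log_baseline": e.log_baseline,
                "species_shift": dict(e.species_shift),
                "sex_shift": e.sex_shift,
                "env_shift": dict(e.env_shift),
                "sigma": e.sigma,
                "lloq": e.lloq,
                "uloq": e.uloq,
                "units": e.units,
            }
            for e in config.effects
        ],
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_scenario(path: str | Path) -> ScenarioConfig:
    doc = yaml.safe_load(Path(path).read_text())
    effects = tuple(EffectSpec(**e) for e in doc["effects"])
    return ScenarioConfig(
        effects=effects,
        group_sizes=doc["group_sizes"],
        sex_counts={g: tuple(mf) for g, mf in doc["sex_counts"].items()},
        seed=doc["seed"],
        name=doc.get("name", "custom"),
    )
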