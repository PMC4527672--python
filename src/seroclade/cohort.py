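"""Cohort data model and delimited-text I/O with censoring-preserving tokens.

A cohort is a set of subjects (species, wild/captive environment, sex, age,
weight) together with their serum biomarker measurements.  Clinical-chemistry
assays report values outside their quantification range only as "<bound" or
">bound"; those censored observations are first-class here and survive a
write/read round trip bit-identically.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Censor",
    "CensoredValue",
    "Subject",
    "GroupKey",
    "Cohort",
    "Dialect",
    "CohortError",
    "SPECIES",
    "ENVIRONMENTS",
    "SEXES",
    "DEFAULT_GROUPS",
    "parse_value",
    "read_cohort",
    "write_cohort",
]

SPECIES = ("human", "bonobo", "chimp_central", "chimp_west", "rhesus")
ENVIRONMENTS = ("wild_born", "captive_born")
SEXES = ("male", "female")

#: Default group vocabulary: short code -> (species, environment).  The codes
#: combine a species abbreviation with the ISO 3166 country of origin.  Humans
#: (healthy volunteers from Germany) fall in the non-wild stratum by convention.
DEFAULT_GROUPS: Mapping[str, tuple[str, str]] = {
    "Rh-DE": ("rhesus", "captive_born"),
    "B-CD": ("bonobo", "wild_born"),
    "B-DE": ("bonobo", "captive_born"),
    "Ch-CG": ("chimp_central", "wild_born"),
    "Ch-SL": ("chimp_west", "wild_born"),
    "Ch-DE": ("chimp_west", "captive_born"),
    "H-DE": ("human", "captive_born"),
}


class CohortError(ValueError):
    """Raised for invalid cohort contents or unparseable input files."""


class Censor(str, Enum):
    """Censoring state of a measurement relative to the assay's range."""

    EXACT = "exact"
    BELOW = "below"   # reported as "<bound": true value under the LLOQ
    ABOVE = "above"   # reported as ">bound": true value over the ULOQ


_CENSOR_OFFSET = {Censor.BELOW: -1, Censor.EXACT: 0, Censor.ABOVE: 1}

# C-locale float: no thousands separators, decimal point only.
_NUMBER_RE = re.compile(r"[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?")
_TOKEN_RE = re.compile(rf"^\s*(?P<rel>[<>]?)\s*(?P<num>{_NUMBER_RE.pattern})\s*$")


@dataclass(frozen=True)
class CensoredValue:
    """A measurement that is exact, below-LLOQ, or above-ULOQ.

    For censored states ``value`` holds the quantification bound itself,
    e.g. ``CensoredValue(1.71, Censor.BELOW)`` for the token "<1.71".
    """

    value: float
    censor: Censor = Censor.EXACT

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise CohortError(f"measurement must be finite and >= 0, got {self.value!r}")
        object.__setattr__(self, "censor", Censor(self.censor))

    @property
    def is_censored(self) -> bool:
        return self.censor is not Censor.EXACT

    def sort_key(self) -> tuple[float, int]:
        """Key realising the censored total preorder.

        Below-censored values at bound b rank strictly under any exact value
        >= b (and tie among themselves); above-censored symmetrically.  An
        exact value equal to a bound ranks above the below-censored block.
        """
        return (self.value, _CENSOR_OFFSET[self.censor])

    def render(self) -> str:
        num = repr(float(self.value))
        if num.endswith(".0"):
            num = num[:-2]
        if self.censor is Censor.BELOW:
            return f"<{num}"
        if self.censor is Censor.ABOVE:
            return f">{num}"
        return num

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.render()


def parse_value(cell: str) -> Optional[CensoredValue]:
    """Parse a value cell: numeric, "<x", ">x" (optional space), or empty.

    Empty/whitespace cells mean *missing* and return None.  Anything else that
    is not a plain C-locale number with an optional censor prefix — including
    locale-style "1,234" — is a hard error.
    """
    if cell is None or cell.strip() == "":
        return None
    m = _TOKEN_RE.match(cell)
    if m is None:
        raise CohortError(f"cannot parse measurement cell {cell!r}")
    rel = m.group("rel")
    value = float(m.group("num"))
    censor = {"": Censor.EXACT, "<": Censor.BELOW, ">": Censor.ABOVE}[rel]
    return CensoredValue(value, censor)


@dataclass(frozen=True)
class Subject:
    subject_id: str
    species: str
    environment: str
    sex: str
    age_years: Optional[float] = None
    weight_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise CohortError(f"unknown species {self.species!r}; expected one of {SPECIES}")
        if self.environment not in ENVIRONMENTS:
            raise CohortError(f"unknown environment {self.environment!r}")
        if self.sex not in SEXES:
            raise CohortError(f"unknown sex {self.sex!r}")
        if self.age_years is not None and (not math.isfinite(self.age_years) or self.age_years < 0):
            raise CohortError(f"age_years must be >= 0, got {self.age_years!r}")
        if self.weight_kg is not None and (not math.isfinite(self.weight_kg) or self.weight_kg <= 0):
            raise CohortError(f"weight_kg must be > 0, got {self.weight_kg!r}")


@dataclass(frozen=True)
class GroupKey:
    """A (species, environment) stratum with its short label."""

    label: str
    species: str
    environment: str


class Cohort:
    """Subjects plus their biomarker measurements.

    Measurements live in a mapping ``(subject_id, biomarker) -> CensoredValue``;
    a missing key means the marker was not determined for that subject, which
    is distinct from a censored value.
    """

    def __init__(self, groups: Mapping[str, tuple[str, str]] | None = None) -> None:
        vocab = DEFAULT_GROUPS if groups is None else groups
        self.groups: dict[str, GroupKey] = {
            label: GroupKey(label, sp, env) for label, (sp, env) in vocab.items()
        }
        pairs = [(g.species, g.environment) for g in self.groups.values()]
        if len(set(pairs)) != len(pairs):
            raise CohortError("group vocabulary is not a bijection label <-> (species, environment)")
        self._by_pair = {(g.species, g.environment): g for g in self.groups.values()}
        self.subjects: dict[str, Subject] = {}
        self.measurements: dict[tuple[str, str], CensoredValue] = {}
        self.biomarkers: dict[str, str] = {}  # name -> units

    # -- construction -----------------------------------------------------

    def register_biomarker(self, name: str, units: str = "") -> None:
        existing = self.biomarkers.get(name)
        if existing not in (None, units) and units != "":
            raise CohortError(f"conflicting units for biomarker {name!r}: {existing!r} vs {units!r}")
        if existing in (None, ""):
            self.biomarkers[name] = units

    def add_subject(self, subject: Subject) -> None:
        if subject.subject_id in self.subjects:
            raise CohortError(f"duplicate subject_id {subject.subject_id!r}")
        if (subject.species, subject.environment) not in self._by_pair:
            raise CohortError(
                f"(species, environment) = {(subject.species, subject.environment)} has no "
                f"group label in the vocabulary {sorted(self.groups)}"
            )
        self.subjects[subject.subject_id] = subject

    def add_measurement(self, subject_id: str, biomarker: str, value: CensoredValue) -> None:
        if subject_id not in self.subjects:
            raise CohortError(f"measurement for unknown subject {subject_id!r}")
        key = (subject_id, biomarker)
        if key in self.measurements:
            raise CohortError(f"duplicate measurement for (subject={subject_id!r}, biomarker={biomarker!r})")
        if biomarker not in self.biomarkers:
            self.register_biomarker(biomarker)
        self.measurements[key] = value

    # -- queries ----------------------------------------------------------

    def group_label(self, subject_id: str) -> str:
        s = self.subjects[subject_id]
        return self._by_pair[(s.species, s.environment)].label

    def subjects_in(
        self,
        *,
        label: str | None = None,
        species: str | Iterable[str] | None = None,
        environment: str | None = None,
        sex: str | None = None,
    ) -> list[Subject]:
        if label is not None:
            if label not in self.groups:
                raise CohortError(f"unknown group label {label!r}; vocabulary: {sorted(self.groups)}")
            g = self.groups[label]
            species, environment = g.species, g.environment
        if isinstance(species, str):
            species = {species}
        elif species is not None:
            species = set(species)
        out = []
        for s in self.subjects.values():
            if species is not None and s.species not in species:
                continue
            if environment is not None and s.environment != environment:
                continue
            if sex is not None and s.sex != sex:
                continue
            out.append(s)
        return out

    def values(self, subjects: Sequence[Subject] | Sequence[str], biomarker: str) -> list[CensoredValue]:
        """Measurements of ``biomarker`` for the given subjects; missing skipped."""
        out = []
        for s in subjects:
            sid = s if isinstance(s, str) else s.subject_id
            v = self.measurements.get((sid, biomarker))
            if v is not None:
                out.append(v)
        return out

    def group_values(self, label: str, biomarker: str) -> list[CensoredValue]:
        return self.values(self.subjects_in(label=label), biomarker)

    def species_values(self, species: str | Iterable[str], biomarker: str) -> list[CensoredValue]:
        """All measurements for one or more species, environments pooled."""
        return self.values(self.subjects_in(species=species), biomarker)

    @property
    def biomarker_names(self) -> list[str]:
        return sorted(self.biomarkers)

    def n_subjects(self) -> int:
        return len(self.subjects)

    def validate(self) -> None:
        for (sid, marker) in self.measurements:
            if sid not in self.subjects:
                raise CohortError(f"measurement references unknown subject {sid!r}")
            if marker not in self.biomarkers:
                raise CohortError(f"measurement references unregistered biomarker {marker!r}")
        # below/above bounds must be consistent per biomarker
        for marker in self.biomarkers:
            lo = [v.value for (_, m), v in self.measurements.items() if m == marker and v.censor is Censor.BELOW]
            hi = [v.value for (_, m), v in self.measurements.items() if m == marker and v.censor is Censor.ABOVE]
            if lo and hi and max(lo) >= min(hi):
                raise CohortError(
                    f"biomarker {marker!r}: below-censor bound {max(lo)} >= above-censor bound {min(hi)}"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.subjects == other.subjects
            and self.measurements == other.measurements
            and self.biomarkers == other.biomarkers
            and self.groups == other.groups
        )


# -- delimited-text I/O ----------------------------------------------------

_LONG_COLUMNS = ["subject_id", "group", "sex", "age_years", "weight_kg", "biomarker", "units", "value"]
_WIDE_META = ["subject_id", "group", "sex", "age_years", "weight_kg"]


@dataclass
class Dialect:
    """Declared file layout; never sniffed.

    ``fmt`` is "long" (one row per subject x biomarker) or "wide" (one row per
    subject, one column per biomarker).  ``units`` supplies the biomarker
    registry for wide files, which have no units column.
    """

    fmt: str = "long"
    sep: str = "\t"
    groups: Mapping[str, tuple[str, str]] | None = None
    units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fmt not in ("long", "wide"):
            raise CohortError(f"dialect fmt must be 'long' or 'wide', got {self.fmt!r}")


def _parse_optional_float(cell: str, what: str, where: str) -> Optional[float]:
    if cell is None or cell.strip() == "":
        return None
    if _TOKEN_RE.match(cell) is None or cell.strip()[0] in "<>":
        raise CohortError(f"cannot parse {what} {cell!r} at {where}")
    return float(cell)


def read_cohort(path: str | Path, dialect: Dialect | None = None) -> Cohort:
    """Read a cohort from a delimited text file according to ``dialect``."""
    dialect = dialect or Dialect()
    cohort = Cohort(groups=dialect.groups)
    for name, units in dialect.units.items():
        cohort.register_biomarker(name, units)
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.sep)
        rows = list(reader)
    if not rows:
        raise CohortError(f"{path}: empty file")
    header = rows[0]
    if dialect.fmt == "long":
        _read_long(cohort, header, rows[1:], path)
    else:
        _read_wide(cohort, header, rows[1:], path)
    cohort.validate()
    return cohort


def _group_lookup(cohort: Cohort, label: str, where: str) -> GroupKey:
    if label not in cohort.groups:
        raise CohortError(
            f"unknown group label {label!r} at {where}; vocabulary: {sorted(cohort.groups)}"
        )
    return cohort.groups[label]


def _read_long(cohort: Cohort, header: list[str], rows: list[list[str]], path: Path) -> None:
    missing = [c for c in ("subject_id", "group", "sex", "biomarker", "value") if c not in header]
    if missing:
        raise CohortError(f"{path}: long-format header lacks columns {missing}")
    idx = {c: header.index(c) for c in header}

    def get(row: list[str], col: str) -> str:
        i = idx.get(col)
        return row[i] if i is not None and i < len(row) else ""

    for rowno, row in enumerate(rows, start=2):
        if not any(cell.strip() for cell in row):
            continue
        where = f"{path}:{rowno}"
        sid = get(row, "subject_id").strip()
        group = _group_lookup(cohort, get(row, "group").strip(), where)
        marker = get(row, "biomarker").strip()
        if sid not in cohort.subjects:
            cohort.add_subject(
                Subject(
                    subject_id=sid,
                    species=group.species,
                    environment=group.environment,
                    sex=get(row, "sex").strip(),
                    age_years=_parse_optional_float(get(row, "age_years"), "age_years", where),
                    weight_kg=_parse_optional_float(get(row, "weight_kg"), "weight_kg", where),
                )
            )
        units = get(row, "units").strip()
        if units:
            cohort.register_biomarker(marker, units)
        try:
            value = parse_value(get(row, "value"))
        except CohortError as exc:
            raise CohortError(f"{where}, column 'value': {exc}") from exc
        if value is not None:
            cohort.add_measurement(sid, marker, value)
        elif marker and marker not in cohort.biomarkers:
            cohort.register_biomarker(marker)


def _read_wide(cohort: Cohort, header: list[str], rows: list[list[str]], path: Path) -> None:
    for col in ("subject_id", "group", "sex"):
        if col not in header:
            raise CohortError(f"{path}: wide-format header lacks column {col!r}")
    marker_cols = [c for c in header if c not in _WIDE_META]
    idx = {c: header.index(c) for c in header}
    for marker in marker_cols:
        cohort.register_biomarker(marker)
    for rowno, row in enumerate(rows, start=2):
        if not any(cell.strip() for cell in row):
            continue
        where = f"{path}:{rowno}"

        def get(col: str) -> str:
            i = idx[col]
            return row[i] if i < len(row) else ""

        sid = get("subject_id").strip()
        group = _group_lookup(cohort, get("group").strip(), where)
        age = _parse_optional_float(get("age_years"), "age_years", where) if "age_years" in idx else None
        weight = _parse_optional_float(get("weight_kg"), "weight_kg", where) if "weight_kg" in idx else None
        cohort.add_subject(
            Subject(sid, group.species, group.environment, get("sex").strip(), age, weight)
        )
        for marker in marker_cols:
            cell = get(marker)
            try:
                value = parse_value(cell)
            except CohortError as exc:
                raise CohortError(f"{where}, column {marker!r}: {exc}") from exc
            if value is not None:
                cohort.add_measurement(sid, marker, value)


def _fmt_float(x: Optional[float]) -> str:
    if x is None:
        return ""
    s = repr(float(x))
    return s[:-2] if s.endswith(".0") else s


def write_cohort(cohort: Cohort, path: str | Path, dialect: Dialect | None = None) -> Path:
    """Write a cohort; ``read_cohort(write_cohort(c))`` is the identity."""
    dialect = dialect or Dialect()
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.sep, lineterminator="\n")
        if dialect.fmt == "long":
            writer.writerow(_LONG_COLUMNS)
            for sid in sorted(cohort.subjects):
                s = cohort.subjects[sid]
                label = cohort.group_label(sid)
                wrote_any = False
                for marker in cohort.biomarker_names:
                    v = cohort.measurements.get((sid, marker))
                    if v is None:
                        continue
                    wrote_any = True
                    writer.writerow(
                        [sid, label, s.sex, _fmt_float(s.age_years), _fmt_float(s.weight_kg),
                         marker, cohort.biomarkers[marker], v.render()]
                    )
                if not wrote_any:  # keep subjects with no measurements
                    writer.writerow(
                        [sid, label, s.sex, _fmt_float(s.age_years), _fmt_float(s.weight_kg), "", "", ""]
                    )
        else:
            markers = cohort.biomarker_names
            writer.writerow(_WIDE_META + markers)
            for sid in sorted(cohort.subjects):
                s = cohort.subjects[sid]
                row = [sid, cohort.group_label(sid), s.sex, _fmt_float(s.age_years), _fmt_float(s.weight_kg)]
                for marker in markers:
                    v = cohort.measurements.get((sid, marker))
                    row.append("" if v is None else v.render())
                writer.writerow(row)
    return path
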