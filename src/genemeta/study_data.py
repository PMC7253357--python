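"""Study records: genotype counts per smoking-status arm, with I/O.

A candidate-gene case-control meta-analysis starts from per-study genotype
counts (here Val/Val, Val/Met, Met/Met at BDNF Val66Met) tabulated separately
for each smoking-status arm. Counts are stored per arm, not per genetic
model, so any model (dominant, recessive, allelic, additive) can be derived
downstream.

The packaged fixture transcribes the eight cohorts of the source
meta-analysis on Val66Met and smoking persistence (current vs never smokers;
N = 10,160). It is shipped both as a CSV data file and as a constant in this
module; the test suite asserts the two agree.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd

from .errors import CountError, SchemaError

__all__ = [
    "GenotypeArm",
    "StudyRecord",
    "StudySet",
    "read_studies",
    "write_studies",
    "load_fixture",
    "validate_study",
    "FIXTURE_ROWS",
]

ANCESTRIES = ("Asian", "Caucasian", "African", "other")

#: Required CSV columns, in canonical write order.
REQUIRED_COLUMNS = (
    "label", "year", "ancestry",
    "cur_vv", "cur_vm", "cur_mm",
    "nev_vv", "nev_vm", "nev_mm",
)
OPTIONAL_ARMS = ("ever", "former")


@dataclass(frozen=True)
class GenotypeArm:
    """Genotype counts for one smoking-status arm.

    Attributes
    ----------
    vv, vm, mm
        Non-negative integer counts of Val/Val, Val/Met and Met/Met carriers.
    """

    vv: int
    vm: int
    mm: int

    def __post_init__(self) -> None:
        for name in ("vv", "vm", "mm"):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool):
                raise CountError(f"count {name!r} must be an integer, got {value!r}")
            if value < 0:
                raise CountError(f"count {name!r} must be non-negative, got {value}")

    def total(self) -> int:
        return self.vv + self.vm + self.mm

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.vv, self.vm, self.mm)


@dataclass(frozen=True)
class StudyRecord:
    """One cohort: genotype counts per arm plus metadata."""

    label: str
    year: int
    ancestry: str
    current: GenotypeArm
    never: GenotypeArm
    ever: Optional[GenotypeArm] = None
    former: Optional[GenotypeArm] = None

    def total(self) -> int:
        """Persistence-analysis sample size (current + never arms)."""
        return self.current.total() + self.never.total()

    def arm(self, name: str) -> Optional[GenotypeArm]:
        return getattr(self, name, None)


@dataclass
class StudySet:
    """An ordered collection of study records (insertion order preserved)."""

    studies: list[StudyRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.studies)

    def __getitem__(self, key) -> StudyRecord:
        if isinstance(key, str):
            for record in self.studies:
                if record.label == key:
                    return record
            raise KeyError(key)
        return self.studies[key]

    @property
    def labels(self) -> list[str]:
        return [record.label for record in self.studies]

    def filter(self, ancestry: Optional[str] = None) -> "StudySet":
        """Subset by ancestry, preserving order."""
        kept = [s for s in self.studies if ancestry is None or s.ancestry == ancestry]
        note = self.provenance
        if ancestry is not None:
            note = f"{note} [ancestry={ancestry}]".strip()
        return StudySet(kept, provenance=note)

    def grand_total(self) -> int:
        return sum(record.total() for record in self.studies)


# Table transcription of the eight cohorts: label, year, ancestry,
# current-arm (vv, vm, mm), never-arm (vv, vm, mm).
FIXTURE_ROWS: tuple[tuple, ...] = (
    ("Lang2007", 2007, "Caucasian", (67, 41, 6), (105, 30, 4)),
    ("Wang2007", 2007, "Asian", (30, 51, 20), (12, 20, 16)),
    ("Montag2008", 2008, "Caucasian", (90, 47, 6), (264, 136, 11)),
    ("Landi2009", 2009, "Caucasian", (879, 521, 62), (458, 277, 41)),
    ("Zhang2012", 2012, "Asian", (81, 177, 64), (74, 156, 76)),
    ("Zhang2015", 2015, "Asian", (215, 456, 173), (114, 253, 107)),
    ("JiangEA2017", 2017, "Caucasian", (623, 235, 17), (508, 210, 23)),
    ("JiangAA2017", 2017, "African", (1543, 121, 1), (1636, 100, 3)),
)


def _parse_count(value, row_label: str, column: str) -> int:
    try:
        as_float = float(value)
    except (TypeError, ValueError):
        raise CountError(
            f"study {row_label!r}, column {column!r}: non-numeric count {value!r}"
        ) from None
    if not as_float.is_integer():
        raise CountError(
            f"study {row_label!r}, column {column!r}: non-integer count {value!r}"
        )
    count = int(as_float)
    if count < 0:
        raise CountError(
            f"study {row_label!r}, column {column!r}: negative count {count}"
        )
    return count


def _arm_from_row(row, prefix: str, label: str) -> GenotypeArm:
    return GenotypeArm(
        vv=_parse_count(row[f"{prefix}_vv"], label, f"{prefix}_vv"),
        vm=_parse_count(row[f"{prefix}_vm"], label, f"{prefix}_vm"),
        mm=_parse_count(row[f"{prefix}_mm"], label, f"{prefix}_mm"),
    )


def read_studies(path, dialect: str = ",") -> StudySet:
    """Read a study table from delimited text (comma default, tab accepted).

    The header must name ``label, year, ancestry, cur_vv, cur_vm, cur_mm,
    nev_vv, nev_vm, nev_mm``; optional ``ever_*`` / ``former_*`` triples are
    picked up when present. Row order is preserved.

    Raises
    ------
    SchemaError
        If a required column is missing.
    CountError
        If a count is negative or not an integer (names row and field).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=dialect, dtype=object)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    records: list[StudyRecord] = []
    for _, row in frame.iterrows():
        label = str(row["label"])
        record = StudyRecord(
            label=label,
            year=int(row["year"]),
            ancestry=str(row["ancestry"]),
            current=_arm_from_row(row, "cur", label),
            never=_arm_from_row(row, "nev", label),
        )
        extras = {}
        for arm_name, prefix in (("ever", "ever"), ("former", "former")):
            cols = [f"{prefix}_{g}" for g in ("vv", "vm", "mm")]
            if all(c in frame.columns for c in cols) and row[cols].notna().all():
                extras[arm_name] = _arm_from_row(row, prefix, label)
        if extras:
            record = StudyRecord(
                label=record.label, year=record.year, ancestry=record.ancestry,
                current=record.current, never=record.never, **extras,
            )
        records.append(record)
    return StudySet(records, provenance=str(path))


def write_studies(studies: StudySet, path, dialect: str = ",") -> None:
    """Write a study set back to delimited text in the canonical schema."""
    rows = []
    has_ever = any(s.ever is not None for s in studies)
    has_former = any(s.former is not None for s in studies)
    for s in studies:
        row = {
            "label": s.label, "year": s.year, "ancestry": s.ancestry,
            "cur_vv": s.current.vv, "cur_vm": s.current.vm, "cur_mm": s.current.mm,
            "nev_vv": s.never.vv, "nev_vm": s.never.vm, "nev_mm": s.never.mm,
        }
        if has_ever and s.ever is not None:
            row.update(ever_vv=s.ever.vv, ever_vm=s.ever.vm, ever_mm=s.ever.mm)
        if has_former and s.former is not None:
            row.update(former_vv=s.former.vv, former_vm=s.former.vm,
                       former_mm=s.former.mm)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=dialect, index=False)


def fixture_path() -> Path:
    """Path to the packaged fixture CSV."""
    return Path(importlib.resources.files("genemeta").joinpath("data/table1.csv"))


def load_fixture() -> StudySet:
    """The eight-cohort Val66Met / smoking-persistence study set (N = 10,160).

    Built from the in-code constant; the packaged CSV carries the same
    numbers and round-trips through :func:`read_studies`.
    """
    records = [
        StudyRecord(label=label, year=year, ancestry=ancestry,
                    current=GenotypeArm(*cur), never=GenotypeArm(*nev))
        for label, year, ancestry, cur, nev in FIXTURE_ROWS
    ]
    return StudySet(records, provenance="packaged fixture: eight-cohort "
                    "BDNF Val66Met smoking-persistence table")


def validate_study(record: StudyRecord,
                   declared_n: Optional[int] = None) -> list[str]:
    """Check record invariants; return findings (empty list = valid).

    Findings, not exceptions: a negative count stored by force, or a
    mismatch between the arm totals and a declared sample size, each yield
    one descriptive string.
    """
    findings: list[str] = []
    for arm_name in ("current", "never", "ever", "former"):
        arm = record.arm(arm_name)
        if arm is None:
            continue
        for genotype in ("vv", "vm", "mm"):
            count = getattr(arm, genotype)
            if count < 0:
                findings.append(
                    f"{record.label}: negative count {arm_name}.{genotype} = {count}"
                )
    if declared_n is not None and record.total() != declared_n:
        findings.append(
            f"{record.label}: current+never total {record.total()} "
            f"!= declared sample size {declared_n}"
        )
    return findings
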