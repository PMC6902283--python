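"""Case-level cohort model, delimited-text I/O, and composite denominators.

A case is one diagnostic referral: a setting (prenatal or pediatric), the
tests performed (karyotyping, aCGH, FISH), the purpose of any FISH panel, and
zero or more abnormal findings.  Because not every case receives every test,
abnormality detection rates are *composite*: each abnormality spectrum has its
own denominator of cases whose testing could have detected that class.

Denominator rules
-----------------
chromosomal : cases tested by karyotype or aCGH, plus FISH-only cases run on
    the common-aneuploidy panel (the panel detects the major numerical
    abnormalities, so those cases were at risk of a chromosomal diagnosis).
pCNV : cases tested by aCGH, plus FISH-only cases run on a targeted
    microdeletion/microduplication panel.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .taxonomy import Finding

__all__ = [
    "Setting",
    "TestModality",
    "FishPurpose",
    "CaseRecord",
    "CohortInventory",
    "DenominatorSet",
    "SchemaConfig",
    "StudyWindow",
    "CohortError",
    "SchemaError",
    "read_cases",
    "write_cases",
    "compute_denominators",
    "inventory",
    "annual_caseload",
    "default_test_census",
]


class Setting(str, Enum):
    PRENATAL = "prenatal"
    PEDIATRIC = "pediatric"


class TestModality(str, Enum):
    KARYOTYPE = "karyotype"
    ACGH = "acgh"
    FISH = "fish"


TestModality.__test__ = False  # not a pytest class despite the name


class FishPurpose(str, Enum):
    ANEUPLOIDY_PANEL = "aneuploidy_panel"
    TARGETED_MICRODELETION = "targeted_microdeletion"
    NONE = "none"


class CohortError(ValueError):
    """Invalid case content."""


class SchemaError(CohortError):
    """Input file does not match the expected column schema."""


@dataclass(frozen=True)
class StudyWindow:
    """Calendar-year bounds a case's year must fall within (inclusive)."""

    start: int = 2008
    end: int = 2017

    def __contains__(self, year: int) -> bool:
        return self.start <= year <= self.end


DEFAULT_WINDOW = StudyWindow()


@dataclass(frozen=True)
class CaseRecord:
    """One diagnostic case."""

    case_id: str
    setting: Setting
    year: int
    tests: frozenset[TestModality]
    fish_purpose: FishPurpose = FishPurpose.NONE
    findings: tuple[Finding, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "tests", frozenset(self.tests))
        object.__setattr__(self, "findings", tuple(self.findings))

    def validate(self, window: StudyWindow = DEFAULT_WINDOW) -> None:
        if not self.tests:
            raise CohortError(f"case {self.case_id}: no tests recorded")
        has_fish = TestModality.FISH in self.tests
        if has_fish and self.fish_purpose is FishPurpose.NONE:
            raise CohortError(
                f"case {self.case_id}: FISH performed but fish_purpose is 'none'"
            )
        if not has_fish and self.fish_purpose is not FishPurpose.NONE:
            raise CohortError(
                f"case {self.case_id}: fish_purpose={self.fish_purpose.value} "
                "but FISH not among tests"
            )
        if self.year not in window:
            raise CohortError(
                f"case {self.case_id}: year {self.year} outside study window "
                f"{window.start}-{window.end}"
            )

    @property
    def is_abnormal(self) -> bool:
        return bool(self.findings)

    # -- denominator eligibility ------------------------------------------
    @property
    def fish_only(self) -> bool:
        return self.tests == frozenset({TestModality.FISH})

    @property
    def chromosomal_eligible(self) -> bool:
        """Counts toward the chromosomal-abnormality denominator."""
        if self.tests & {TestModality.KARYOTYPE, TestModality.ACGH}:
            return True
        return self.fish_only and self.fish_purpose is FishPurpose.ANEUPLOIDY_PANEL

    @property
    def pcnv_eligible(self) -> bool:
        """Counts toward the pCNV denominator."""
        if TestModality.ACGH in self.tests:
            return True
        return self.fish_only and self.fish_purpose is FishPurpose.TARGETED_MICRODELETION


@dataclass(frozen=True)
class DenominatorSet:
    """Composite denominators for one setting."""

    setting: Setting
    chromosomal: int
    pcnv: int
    total: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "setting": self.setting.value,
                "chromosomal_denominator": self.chromosomal,
                "pcnv_denominator": self.pcnv,
                "total_cases": self.total,
            },
            indent=2,
        )


@dataclass
class CohortInventory:
    """Case counts per (setting, test combination, FISH purpose)."""

    counts: dict[tuple[Setting, frozenset[TestModality], FishPurpose], int]
    totals: dict[Setting, int]
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "setting": setting.value,
                "tests": "|".join(sorted(t.value for t in tests)),
                "fish_purpose": purpose.value,
                "count": count,
            }
            for (setting, tests, purpose), count in sorted(
                self.counts.items(),
                key=lambda kv: (kv[0][0].value, -kv[1], kv[0][2].value),
            )
        ]
        return pd.DataFrame(rows, columns=["setting", "tests", "fish_purpose", "count"])

    def total(self, setting: Setting) -> int:
        return self.totals.get(setting, 0)


@dataclass(frozen=True)
class SchemaConfig:
    """Column mapping and delimiters for the case file format."""

    delimiter: str = ","
    multi_value_sep: str = "|"
    case_id: str = "case_id"
    setting: str = "setting"
    year: str = "year"
    tests: str = "tests"
    fish_purpose: str = "fish_purpose"
    findings: str = "findings"

    @property
    def columns(self) -> tuple[str, ...]:
        return (
            self.case_id,
            self.setting,
            self.year,
            self.tests,
            self.fish_purpose,
            self.findings,
        )


DEFAULT_SCHEMA = SchemaConfig()


def _parse_row(row: pd.Series, config: SchemaConfig, rownum: int) -> CaseRecord:
    def enum_value(cls, token: str, column: str):
        try:
            return cls(token)
        except ValueError:
            raise CohortError(
                f"row {rownum}: unknown {column} token {token!r}"
            ) from None

    tests_cell = str(row[config.tests]).strip()
    tests = frozenset(
        enum_value(TestModality, tok.strip(), "test")
        for tok in tests_cell.split(config.multi_value_sep)
        if tok.strip()
    )
    purpose_cell = str(row[config.fish_purpose]).strip() or "none"
    purpose = enum_value(FishPurpose, purpose_cell, "fish_purpose")
    findings_cell = row[config.findings]
    findings: tuple[Finding, ...] = ()
    if isinstance(findings_cell, str) and findings_cell.strip():
        try:
            findings = tuple(
                Finding.from_token(tok.strip())
                for tok in findings_cell.split(config.multi_value_sep)
                if tok.strip()
            )
        except ValueError as exc:
            raise CohortError(f"row {rownum}: {exc}") from exc
    try:
        year = int(row[config.year])
    except (TypeError, ValueError):
        raise CohortError(f"row {rownum}: year {row[config.year]!r} is not an integer")
    return CaseRecord(
        case_id=str(row[config.case_id]),
        setting=enum_value(Setting, str(row[config.setting]).strip(), "setting"),
        year=year,
        tests=tests,
        fish_purpose=purpose,
        findings=findings,
    )


def read_cases(
    path: Union[str, Path],
    config: SchemaConfig = DEFAULT_SCHEMA,
    window: StudyWindow = DEFAULT_WINDOW,
) -> list[CaseRecord]:
    """Read a delimited case file into validated records, preserving order.

    Malformed rows raise :class:`CohortError` carrying the 1-based data row
    number; a missing mandatory column raises :class:`SchemaError`.
    """
    frame = pd.read_csv(path, sep=config.delimiter, dtype=str, keep_default_na=False)
    missing = [col for col in config.columns if col not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    cases = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        record = _parse_row(row, config, i)
        try:
            record.validate(window)
        except CohortError as exc:
            raise CohortError(f"row {i}: {exc}") from exc
        cases.append(record)
    return cases


def write_cases(
    cases: Sequence[CaseRecord],
    path: Union[str, Path],
    config: SchemaConfig = DEFAULT_SCHEMA,
) -> None:
    """Write cases in the documented schema (stable column order)."""
    rows = []
    for case in cases:
        rows.append(
            {
                config.case_id: case.case_id,
                config.setting: case.setting.value,
                config.year: case.year,
                config.tests: config.multi_value_sep.join(
                    sorted(t.value for t in case.tests)
                ),
                config.fish_purpose: case.fish_purpose.value,
                config.findings: config.multi_value_sep.join(
                    f.token() for f in case.findings
                ),
            }
        )
    frame = pd.DataFrame(rows, columns=list(config.columns))
    frame.to_csv(path, sep=config.delimiter, index=False)


def compute_denominators(
    cases: Sequence[CaseRecord], setting: Setting
) -> DenominatorSet:
    """Composite denominators for one setting.

    An empty case list yields zero denominators; a case from the wrong setting
    raises :class:`CohortError`.
    """
    chromosomal = pcnv = total = 0
    for case in cases:
        if case.setting is not setting:
            raise CohortError(
                f"case {case.case_id} is {case.setting.value}, expected {setting.value}"
            )
        total += 1
        chromosomal += case.chromosomal_eligible
        pcnv += case.pcnv_eligible
    return DenominatorSet(setting=setting, chromosomal=chromosomal, pcnv=pcnv, total=total)


def inventory(cases: Sequence[CaseRecord]) -> CohortInventory:
    """Tally cases per (setting, test combination, FISH purpose).

    Duplicated case ids are counted (the census is per referral) but reported
    in the inventory's warnings channel.
    """
    counts: Counter = Counter()
    totals: Counter = Counter()
    seen: Counter = Counter()
    for case in cases:
        counts[(case.setting, case.tests, case.fish_purpose)] += 1
        totals[case.setting] += 1
        seen[case.case_id] += 1
    warns = [
        f"case_id {cid!r} appears {n} times" for cid, n in sorted(seen.items()) if n > 1
    ]
    inv = CohortInventory(counts=dict(counts), totals=dict(totals), warnings=warns)
    for message in warns:
        warnings.warn(message, stacklevel=2)
    return inv


def annual_caseload(cases: Sequence[CaseRecord]) -> pd.DataFrame:
    """Per-year per-modality caseload.

    A case tested by k modalities contributes one count to each of its k
    modality rows but only once to the setting-year ``total`` row.
    """
    tallies: Counter = Counter()
    for case in cases:
        for test in case.tests:
            tallies[(case.setting.value, case.year, test.value)] += 1
        tallies[(case.setting.value, case.year, "total")] += 1
    rows = [
        {"setting": s, "year": y, "modality": m, "count": n}
        for (s, y, m), n in sorted(tallies.items())
    ]
    return pd.DataFrame(rows, columns=["setting", "year", "modality", "count"])


def default_test_census() -> pd.DataFrame:
    """The reference cohort's test-combination census shipped as package data."""
    path = resources.files("cytoyield.data").joinpath("test_census.tsv")
    with path.open("r", encoding="utf-8") as handle:
        return pd.read_csv(handle, sep="\t", comment="#")
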