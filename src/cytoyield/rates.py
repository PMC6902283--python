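"""Composite detection rates, relative frequencies, and spectrum tables.

ADR (abnormality detection rate) is abnormal cases over tested cases, as a
percent.  It is *composite* because the chromosomal and pCNV spectra use
different denominators (see :mod:`cytoyield.cohort`).  RF (relative frequency)
is a category's abnormal cases over all abnormal cases of its spectrum.

Values are kept at full precision internally; 2-decimal half-up strings are
produced only at rendering time.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._render import render_ratio_percent
from .classify import CaseClassification
from .cohort import CaseRecord, DenominatorSet, Setting
from .taxonomy import AbnormalityCategory

__all__ = [
    "UndefinedRateError",
    "RateEntry",
    "SpectrumTable",
    "ChiSquareResult",
    "adr",
    "rf",
    "chi_square_2x2",
    "build_chromosomal_spectrum",
    "build_pcnv_spectrum",
    "CHROMOSOMAL_LAYOUT",
]


class UndefinedRateError(ZeroDivisionError):
    """Rate requested with a zero denominator."""


def adr(abnormal_count: int, denominator: int) -> float:
    """Abnormality detection rate in percent, full precision."""
    if denominator <= 0:
        raise UndefinedRateError("ADR undefined: denominator is 0")
    if not 0 <= abnormal_count <= denominator:
        raise ValueError(
            f"abnormal_count {abnormal_count} outside [0, {denominator}]"
        )
    return 100.0 * abnormal_count / denominator


def rf(category_count: int, spectrum_total: int) -> float:
    """Relative frequency in percent within a spectrum, full precision."""
    if spectrum_total <= 0:
        raise UndefinedRateError("RF undefined: spectrum total is 0")
    if not 0 <= category_count <= spectrum_total:
        raise ValueError(
            f"category_count {category_count} outside [0, {spectrum_total}]"
        )
    return 100.0 * category_count / spectrum_total


@dataclass(frozen=True)
class RateEntry:
    """One row of a spectrum table."""

    key: str
    label: str
    kind: str  # leaf | subtotal | total | grand_total
    count: int
    denominator: int
    spectrum_total: int

    @property
    def adr(self) -> float:
        return adr(self.count, self.denominator)

    @property
    def rf(self) -> float:
        return rf(self.count, self.spectrum_total)

    @property
    def adr_str(self) -> str:
        return render_ratio_percent(self.count, self.denominator)

    @property
    def rf_str(self) -> str:
        return render_ratio_percent(self.count, self.spectrum_total)


@dataclass
class SpectrumTable:
    """Ordered rate entries for one spectrum in one setting."""

    setting: Setting
    spectrum: str  # "chromosomal" | "pcnv"
    rows: list[RateEntry]
    denominator: int
    spectrum_total: int

    def entry(self, key: str) -> RateEntry:
        for row in self.rows:
            if row.key == key:
                return row
        raise KeyError(f"no row {key!r} in {self.spectrum} spectrum")

    def to_frame(self, rendered: bool = True) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec = {
                "row": row.key,
                "label": row.label,
                "kind": row.kind,
                "count": row.count,
            }
            if row.count == 0:
                rec["adr"] = "" if rendered else 0.0
                rec["rf"] = "" if rendered else 0.0
            elif rendered:
                rec["adr"], rec["rf"] = row.adr_str, row.rf_str
            else:
                rec["adr"], rec["rf"] = row.adr, row.rf
            records.append(rec)
        return pd.DataFrame(records, columns=["row", "label", "kind", "count", "adr", "rf"])


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    p_value: float
    degrees_of_freedom: int
    table: tuple[tuple[int, int], tuple[int, int]]
    warnings: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def chi_square_2x2(
    count_a: int,
    denom_a: int,
    count_b: int,
    denom_b: int,
    correction: bool = False,
) -> ChiSquareResult:
    """Pearson chi-square on the 2x2 detection table of two groups.

    Continuity correction is off by default (available behind the flag).  An
    expected cell below 1 is reported on the result's warnings channel but
    the statistic is still returned.
    """
    if not (0 <= count_a < denom_a and 0 <= count_b < denom_b):
        raise ValueError("need denominators > counts >= 0")
    table = np.array([[count_a, denom_a - count_a], [count_b, denom_b - count_b]])
    statistic, p_value, dof, expected = stats.chi2_contingency(
        table, correction=correction
    )
    warns = []
    if (expected < 1).any():
        message = "expected cell count below 1; chi-square approximation is poor"
        warns.append(message)
        warnings.warn(message, stacklevel=2)
    return ChiSquareResult(
        statistic=float(statistic),
        p_value=float(p_value),
        degrees_of_freedom=int(dof),
        table=((int(table[0, 0]), int(table[0, 1])), (int(table[1, 0]), int(table[1, 1]))),
        warnings=tuple(warns),
    )


# --------------------------------------------------------------------------
# spectrum builders
# --------------------------------------------------------------------------

_C = AbnormalityCategory

#: Row layout of the chromosomal spectrum: (key, label, kind, member leaves).
#: Subtotals/totals aggregate their member leaves; order mirrors the
#: reference table.
CHROMOSOMAL_LAYOUT: list[tuple[str, str, str, frozenset[AbnormalityCategory]]] = [
    ("xxy", "47,XXY", "leaf", frozenset({_C.XXY})),
    ("xyy", "47,XYY", "leaf", frozenset({_C.XYY})),
    ("other_male_sca", "Other male SCA", "leaf", frozenset({_C.OTHER_MALE_SCA})),
    ("monosomy_x", "45,X", "leaf", frozenset({_C.MONOSOMY_X})),
    ("xxx", "47,XXX", "leaf", frozenset({_C.XXX})),
    ("other_female_sca", "Other female SCA", "leaf", frozenset({_C.OTHER_FEMALE_SCA})),
    (
        "sca_subtotal",
        "Sex chromosome aneuploidy",
        "subtotal",
        frozenset(
            {_C.XXY, _C.XYY, _C.OTHER_MALE_SCA, _C.MONOSOMY_X, _C.XXX, _C.OTHER_FEMALE_SCA}
        ),
    ),
    ("trisomy21", "Trisomy 21", "leaf", frozenset({_C.TRISOMY_21})),
    ("trisomy18", "Trisomy 18", "leaf", frozenset({_C.TRISOMY_18})),
    ("trisomy13", "Trisomy 13", "leaf", frozenset({_C.TRISOMY_13})),
    (
        "other_autosomal_aneuploidy",
        "Other aneuploidy",
        "leaf",
        frozenset({_C.OTHER_AUTOSOMAL_ANEUPLOIDY}),
    ),
    (
        "autosomal_subtotal",
        "Autosomal aneuploidy",
        "subtotal",
        frozenset(
            {_C.TRISOMY_21, _C.TRISOMY_18, _C.TRISOMY_13, _C.OTHER_AUTOSOMAL_ANEUPLOIDY}
        ),
    ),
    ("polyploidy", "Triploid & tetraploid", "leaf", frozenset({_C.TRIPLOIDY, _C.TETRAPLOIDY})),
    (
        "numerical_total",
        "Numerical abnormality",
        "total",
        frozenset(c for c in _C if c.group.value == "numerical"),
    ),
    (
        "robertsonian_balanced",
        "Robertsonian translocations",
        "leaf",
        frozenset({_C.ROBERTSONIAN_BALANCED}),
    ),
    ("other_balanced", "Other balanced", "leaf", frozenset({_C.OTHER_BALANCED})),
    (
        "balanced_subtotal",
        "Balanced rearrangements",
        "subtotal",
        frozenset({_C.ROBERTSONIAN_BALANCED, _C.OTHER_BALANCED}),
    ),
    (
        "unbalanced_rearrangement",
        "Unbalanced rearrangements",
        "leaf",
        frozenset({_C.UNBALANCED_REARRANGEMENT}),
    ),
    (
        "structural_total",
        "Structural abnormality",
        "total",
        frozenset(c for c in _C if c.group.value == "structural"),
    ),
    (
        "all_chromosomal",
        "All chromosomal abnormalities",
        "grand_total",
        frozenset(c for c in _C if c.group.value in ("numerical", "structural")),
    ),
]


def _pair_cases(
    cases: Sequence[CaseRecord],
    classifications: Sequence[CaseClassification],
    setting: Setting,
) -> list[tuple[CaseRecord, CaseClassification]]:
    if len(cases) != len(classifications):
        raise ValueError("cases and classifications must align one-to-one")
    return [
        (case, cls)
        for case, cls in zip(cases, classifications)
        if case.setting is setting
    ]


def build_chromosomal_spectrum(
    cases: Sequence[CaseRecord],
    classifications: Sequence[CaseClassification],
    denominators: DenominatorSet,
    setting: Optional[Setting] = None,
) -> SpectrumTable:
    """Chromosomal-abnormality spectrum for one setting.

    A case contributes to the leaf of each chromosomal category it carries
    (once per leaf) and once to every aggregate row containing that leaf; the
    ADR denominator is the chromosomal composite denominator, and only
    denominator-eligible cases are counted in numerators.
    """
    setting = setting or denominators.setting
    paired = _pair_cases(cases, classifications, setting)
    leaf_counts: Counter = Counter()
    abnormal_cases = 0
    for case, cls in paired:
        if not case.chromosomal_eligible:
            continue
        leaves = {
            c
            for c in cls.categories
            if c.group.value in ("numerical", "structural")
        }
        if leaves:
            abnormal_cases += 1
        for leaf in leaves:
            leaf_counts[leaf] += 1
    rows = []
    for key, label, kind, members in CHROMOSOMAL_LAYOUT:
        count = sum(leaf_counts[m] for m in members)
        if kind == "leaf" and count == 0 and key in ("other_male_sca", "other_female_sca"):
            continue  # rows absent from the reference layout unless populated
        rows.append(
            RateEntry(
                key=key,
                label=label,
                kind=kind,
                count=count,
                denominator=denominators.chromosomal,
                spectrum_total=abnormal_cases,
            )
        )
    return SpectrumTable(
        setting=setting,
        spectrum="chromosomal",
        rows=rows,
        denominator=denominators.chromosomal,
        spectrum_total=abnormal_cases,
    )


def build_pcnv_spectrum(
    cases: Sequence[CaseRecord],
    classifications: Sequence[CaseClassification],
    denominators: DenominatorSet,
    setting: Optional[Setting] = None,
    locus_order: Optional[Sequence[str]] = None,
) -> SpectrumTable:
    """pCNV spectrum for one setting.

    Recurrent-disorder rows are grouped by locus and split by dosage: a case
    carrying only deletions at a locus lands in the ``del`` row, only
    duplications in ``dup``, both in ``del_and_dup``; the locus total is the
    union.  Sporadic rows count cases with subtelomeric / interstitial pCNVs.
    The ADR denominator is the pCNV composite denominator.
    """
    setting = setting or denominators.setting
    paired = _pair_cases(cases, classifications, setting)

    locus_cases: dict[str, dict[str, set[str]]] = {}
    sporadic: Counter = Counter()
    abnormal_cases = 0
    recurrent_cases: set[str] = set()
    for case, cls in paired:
        if not case.pcnv_eligible:
            continue
        if cls.pcnv_abnormal:
            abnormal_cases += 1
        if _C.SUBTELOMERIC_PCNV in cls.categories:
            sporadic["subtelomeric"] += 1
        if _C.INTERSTITIAL_PCNV in cls.categories:
            sporadic["interstitial"] += 1
        for locus_label, dosage in set(cls.locus_hits):
            slot = locus_cases.setdefault(locus_label, {"del": set(), "dup": set()})
            slot[dosage.value].add(case.case_id)
            recurrent_cases.add(case.case_id)

    if locus_order is None:
        locus_order = sorted(
            locus_cases,
            key=lambda lab: -len(locus_cases[lab]["del"] | locus_cases[lab]["dup"]),
        )

    denominator = denominators.pcnv
    rows: list[RateEntry] = []

    def entry(key: str, label: str, kind: str, count: int) -> RateEntry:
        return RateEntry(
            key=key,
            label=label,
            kind=kind,
            count=count,
            denominator=denominator,
            spectrum_total=abnormal_cases,
        )

    for label in locus_order:
        slot = locus_cases.get(label, {"del": set(), "dup": set()})
        only_del = slot["del"] - slot["dup"]
        only_dup = slot["dup"] - slot["del"]
        both = slot["del"] & slot["dup"]
        total = slot["del"] | slot["dup"]
        if not total:
            continue
        rows.append(entry(f"{label}_total", label, "locus_total", len(total)))
        if only_del:
            rows.append(entry(f"{label}_del", f"{label} deletion", "del", len(only_del)))
        if only_dup:
            rows.append(entry(f"{label}_dup", f"{label} duplication", "dup", len(only_dup)))
        if both:
            rows.append(
                entry(f"{label}_del_and_dup", f"{label} del & dup", "del_and_dup", len(both))
            )
    rows.append(
        entry("recurrent_total", "Recurrent genomic disorders", "recurrent_total", len(recurrent_cases))
    )
    rows.append(entry("subtelomeric", "Subtelomeric pCNVs", "sporadic", sporadic["subtelomeric"]))
    rows.append(entry("interstitial", "Interstitial pCNVs", "sporadic", sporadic["interstitial"]))
    rows.append(
        entry(
            "sporadic_total",
            "Sporadic pCNVs",
            "sporadic_total",
            sporadic["subtelomeric"] + sporadic["interstitial"],
        )
    )
    rows.append(entry("all_pcnv", "All pCNVs", "grand_total", abnormal_cases))
    return SpectrumTable(
        setting=setting,
        spectrum="pcnv",
        rows=rows,
        denominator=denominator,
        spectrum_total=abnormal_cases,
    )
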