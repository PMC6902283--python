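"""Population-level diagnostic efficacy.

A served-population model converts 10-year detected case counts into cases
per 10,000 newborns: with a served population P, annual birth rate b and a
Y-year window, the window contains P*b*Y newborns, i.e. P*b*Y/10,000 units of
10,000.  Efficacy for an abnormality is detected-per-10k over
expected-per-10k (the newborn incidence times 10,000), banded as highly
effective (>=90%), variably effective (50-90%) or under detection (<50%).

Two computation modes are exposed.  ``exact`` keeps full precision
everywhere.  ``replicate`` reproduces the reference table's arithmetic: the
expected and detected columns are first rendered at each row's tabulated
precision and the efficacy is taken on the rendered values, with the handful
of documented aggregate overrides shipped in ``data/efficacy_profile.tsv``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

from ._catalog import load_incidence_catalog
from ._render import format_fixed, round_half_up
from .calibration import deletion_adr_count
from .cohort import Setting
from .rates import SpectrumTable

__all__ = [
    "EfficacyBand",
    "ServedPopulationModel",
    "EfficacyRow",
    "CoverageEstimate",
    "detected_per_10k",
    "expected_per_10k",
    "efficacy_percent",
    "efficacy_band",
    "ds_dgs_ratio",
    "render_ratio",
    "estimate_coverage",
    "build_efficacy_table",
]


class EfficacyBand(str, Enum):
    HIGHLY_EFFECTIVE = "highly_effective"
    VARIABLE = "variable"
    UNDER_DETECTION = "under_detection"


@dataclass(frozen=True)
class ServedPopulationModel:
    """Served population size, annual birth rate, and study-window length."""

    population: float = 2_000_000
    birth_rate: float = 0.01
    years: float = 10

    def __post_init__(self) -> None:
        if min(self.population, self.birth_rate, self.years) <= 0:
            raise ValueError("population, birth_rate and years must be positive")

    @property
    def newborn_units(self) -> float:
        """Ten-thousands of newborns in the study window."""
        return self.population * self.birth_rate * self.years / 10_000


DEFAULT_MODEL = ServedPopulationModel()


def detected_per_10k(case_count: int, model: ServedPopulationModel = DEFAULT_MODEL) -> float:
    """Detected cases per 10,000 newborns over the study window."""
    units = model.newborn_units
    if units == 0:
        raise ZeroDivisionError("served-population model yields zero newborns")
    return case_count / units


def expected_per_10k(incidence: float) -> float:
    """Expected cases per 10,000 newborns from a newborn incidence fraction."""
    if not 0 < incidence < 1:
        raise ValueError("incidence must be a fraction in (0, 1)")
    return incidence * 10_000


def efficacy_percent(detected: float, expected: float) -> float:
    """Diagnostic efficacy: detected over expected, as a percent."""
    if expected <= 0:
        raise ZeroDivisionError("expected cases must be positive")
    return 100.0 * detected / expected


def efficacy_band(percent: float) -> EfficacyBand:
    if percent >= 90:
        return EfficacyBand.HIGHLY_EFFECTIVE
    if percent >= 50:
        return EfficacyBand.VARIABLE
    return EfficacyBand.UNDER_DETECTION


def ds_dgs_ratio(ds_count: int, dgs_count: int) -> float:
    """Detected Down-syndrome over DiGeorge-deletion cases, a scale-free
    screen for differential under-detection (should sit near the incidence
    ratio, about 4-5, when both are detected proportionally)."""
    if dgs_count <= 0:
        raise ZeroDivisionError("DGS count must be positive for the ratio")
    return ds_count / dgs_count


def render_ratio(value: float) -> str:
    """1-decimal rendering, dropping the decimal above 10."""
    if value > 10:
        return str(int(round_half_up(value, 0)))
    return format_fixed(value, 1)


@dataclass(frozen=True)
class EfficacyRow:
    """One abnormality's efficacy in one setting."""

    key: str
    label: str
    setting: Setting
    incidence_one_in_n: int
    expected: float
    expected_rendered: str
    detected_count: int
    detected: float
    detected_rendered: str
    efficacy: float
    efficacy_rendered: str
    band: EfficacyBand


@dataclass(frozen=True)
class CoverageEstimate:
    """How much of a state's expected caseload the laboratory sees."""

    annual_detected_ds: float
    annual_detected_dgs: float
    statewide_expected_ds: float
    statewide_expected_dgs: float
    implied_served_population: float

    @property
    def ds_fraction(self) -> float:
        return self.annual_detected_ds / self.statewide_expected_ds

    @property
    def dgs_fraction(self) -> float:
        return self.annual_detected_dgs / self.statewide_expected_dgs

    @property
    def detection_fraction_range(self) -> tuple[float, float]:
        fractions = sorted((100 * self.ds_fraction, 100 * self.dgs_fraction))
        return (fractions[0], fractions[1])


def estimate_coverage(
    annual_detected_ds: float,
    annual_detected_dgs: float,
    statewide_births: float,
    ds_one_in_n: float = 830,
    dgs_one_in_n: float = 4000,
    coverage_fraction: float = 0.6,
    state_population: float = 3_600_000,
    expected_overrides: Optional[dict[str, float]] = None,
) -> CoverageEstimate:
    """Fractions of the statewide expected DS and DGS caseload detected.

    Statewide expectations default to births/N; ``expected_overrides`` (keys
    ``"ds"``/``"dgs"``) substitute externally quoted expectations.  The
    implied served population is reported as configured coverage fraction
    times the state population, not solved for.
    """
    if min(annual_detected_ds, annual_detected_dgs, statewide_births) < 0:
        raise ValueError("inputs must be non-negative")
    overrides = expected_overrides or {}
    expected_ds = overrides.get("ds", statewide_births / ds_one_in_n)
    expected_dgs = overrides.get("dgs", statewide_births / dgs_one_in_n)
    return CoverageEstimate(
        annual_detected_ds=annual_detected_ds,
        annual_detected_dgs=annual_detected_dgs,
        statewide_expected_ds=expected_ds,
        statewide_expected_dgs=expected_dgs,
        implied_served_population=coverage_fraction * state_population,
    )


# --------------------------------------------------------------------------
# the efficacy table
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class _ProfileRow:
    key: str
    label: str
    incidence_label: str
    source: str
    exp_dp: int
    det_dp: dict[Setting, int]
    expected_override: Optional[float]
    det_override_ped: Optional[int]
    det_render_override_pre: Optional[float]


def _load_profile() -> list[_ProfileRow]:
    path = resources.files("cytoyield.data").joinpath("efficacy_profile.tsv")
    with path.open("r", encoding="utf-8") as handle:
        lines = [ln for ln in handle if not ln.startswith("#")]
    rows = []
    for row in csv.DictReader(lines, delimiter="\t"):
        def opt(name, cast):
            cell = (row.get(name) or "").strip()
            return cast(cell) if cell else None

        rows.append(
            _ProfileRow(
                key=row["row"],
                label=row["label"],
                incidence_label=row["incidence_label"],
                source=row["source"],
                exp_dp=int(row["exp_dp"]),
                det_dp={
                    Setting.PRENATAL: int(row["det_dp_pre"]),
                    Setting.PEDIATRIC: int(row["det_dp_ped"]),
                },
                expected_override=opt("expected_override", float),
                det_override_ped=opt("det_override_ped", int),
                det_render_override_pre=opt("det_render_override_pre", float),
            )
        )
    return rows


def _detected_count(
    source: str,
    chromosomal: SpectrumTable,
    pcnv: SpectrumTable,
) -> int:
    kind, _, arg = source.partition(":")
    if kind == "leaf":
        return chromosomal.entry(arg.lower()).count
    if kind == "locus_del":
        return deletion_adr_count(pcnv, arg)
    if kind == "aggregate":
        if arg == "all_chromosomal":
            return chromosomal.entry("all_chromosomal").count
        if arg == "recurrent":
            return pcnv.entry("recurrent_total").count
        if arg == "all_pcnv":
            return pcnv.entry("all_pcnv").count
    raise ValueError(f"unknown detected-count source {source!r}")


def build_efficacy_table(
    spectra: dict[Setting, tuple[SpectrumTable, SpectrumTable]],
    model: ServedPopulationModel = DEFAULT_MODEL,
    mode: str = "replicate",
    catalog: Optional[pd.DataFrame] = None,
    detected_overrides: Optional[dict[tuple[Setting, str], int]] = None,
) -> list[EfficacyRow]:
    """Build the efficacy table for both settings.

    ``spectra`` maps each setting to its (chromosomal, pCNV) spectrum pair.
    ``mode`` is ``"replicate"`` (rendered-precision arithmetic plus the
    profile's documented overrides) or ``"exact"`` (full precision, no
    overrides).  Extra ``detected_overrides`` keyed by (setting, row key)
    substitute detected 10-year counts in either mode.
    """
    if mode not in ("replicate", "exact"):
        raise ValueError("mode must be 'replicate' or 'exact'")
    replicate = mode == "replicate"
    catalog = catalog if catalog is not None else load_incidence_catalog()
    eff = catalog[catalog["context"] == "efficacy"].set_index("label")
    detected_overrides = detected_overrides or {}

    rows: list[EfficacyRow] = []
    sum_components: dict[tuple[Setting, str], EfficacyRow] = {}
    for profile in _load_profile():
        try:
            one_in_n = int(eff.loc[profile.incidence_label, "one_in_n"])
        except KeyError:
            raise KeyError(
                f"incidence catalog lacks efficacy entry {profile.incidence_label!r}"
            ) from None
        expected_exact = expected_per_10k(1.0 / one_in_n)
        if replicate and profile.expected_override is not None:
            expected_used = profile.expected_override
        elif replicate:
            expected_used = round_half_up(expected_exact, profile.exp_dp)
        else:
            expected_used = expected_exact
        expected_rendered = format_fixed(expected_used, profile.exp_dp)

        for setting, (chromosomal, pcnv) in spectra.items():
            if profile.source.startswith("sum:"):
                keys = profile.source[4:].split("+")
                members = [sum_components[(setting, k)] for k in keys]
                count = sum(m.detected_count for m in members)
                if replicate:
                    detected_used = sum(float(m.detected_rendered) for m in members)
                else:
                    detected_used = sum(m.detected for m in members)
            else:
                count = _detected_count(profile.source, chromosomal, pcnv)
                if (setting, profile.key) in detected_overrides:
                    count = detected_overrides[(setting, profile.key)]
                elif (
                    replicate
                    and setting is Setting.PEDIATRIC
                    and profile.det_override_ped is not None
                    and profile.det_override_ped <= count
                ):
                    # the override narrows tabulated locus deletions to the
                    # syndrome-confirmed subset, so it never exceeds the count
                    count = profile.det_override_ped
                detected_used = detected_per_10k(count, model)

            dp = profile.det_dp[setting]
            if (
                replicate
                and setting is Setting.PRENATAL
                and profile.det_render_override_pre is not None
                and count > 0
            ):
                detected_render_value = profile.det_render_override_pre
            else:
                detected_render_value = round_half_up(detected_used, dp)
            detected_rendered = format_fixed(detected_render_value, dp)

            det_for_eff = detected_render_value if replicate else detected_used
            value = efficacy_percent(det_for_eff, expected_used)
            rendered = "" if count == 0 else f"{round_half_up(value, 0):.0f}%"
            row = EfficacyRow(
                key=profile.key,
                label=profile.label,
                setting=setting,
                incidence_one_in_n=one_in_n,
                expected=expected_used,
                expected_rendered=expected_rendered,
                detected_count=count,
                detected=detected_used,
                detected_rendered=detected_rendered,
                efficacy=value,
                efficacy_rendered=rendered,
                band=efficacy_band(value),
            )
            rows.append(row)
            sum_components[(setting, profile.key)] = row
    return rows


def efficacy_frame(rows: Sequence[EfficacyRow]) -> pd.DataFrame:
    """Wide one-row-per-abnormality view of an efficacy table."""
    by_key: dict[str, dict] = {}
    for row in rows:
        slot = by_key.setdefault(
            row.key,
            {
                "row": row.key,
                "label": row.label,
                "incidence": f"1/{row.incidence_one_in_n:,}",
                "expected_per_10k": row.expected_rendered,
            },
        )
        prefix = "prenatal" if row.setting is Setting.PRENATAL else "pediatric"
        slot[f"{prefix}_detected_per_10k"] = (
            row.detected_rendered if row.detected_count else ""
        )
        slot[f"{prefix}_efficacy"] = row.efficacy_rendered
    return pd.DataFrame(list(by_key.values()))
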