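"""Prevalence calibration: regressing known prevalence on detection rate.

The idea: for disorders whose population prevalence is established, the
detection rate (ADR) observed in a pediatric diagnostic series is roughly
proportional to prevalence.  Fitting prevalence (percent) on ADR (percent) by
ordinary least squares over a small calibration panel gives a line that can be
inverted into an inexpensive prevalence estimate for *rare* disorders, for
which only an ADR is observable:

    prevalence% = slope * ADR% + intercept

Two calibration panels are used: four autosomal/sex aneuploidies with known
live-birth incidences, and five microdeletion syndromes with reported
prevalences.  The slope test is the usual t transform of the correlation,
t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.

The model/results API follows the statsmodels convention:
``PrevalenceCalibration(...).fit()`` returns a results object carrying the
estimates, their standard errors, diagnostics, ``predict`` and ``summary``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from ._render import round_half_up
from .cohort import Setting
from .rates import SpectrumTable
from ._catalog import load_incidence_catalog

__all__ = [
    "CalibrationPoint",
    "CalibrationLine",
    "PrevalenceEstimate",
    "PrevalenceCalibration",
    "PrevalenceCalibrationResults",
    "ExactFitWarning",
    "OutOfRangeError",
    "slope_p_from_r2",
    "predict_prevalence",
    "build_calibration_sets",
    "ANEUPLOIDY_REFERENCE_LINE",
    "GENOMIC_DISORDER_REFERENCE_LINE",
]


class OutOfRangeError(ValueError):
    """Extrapolated prevalence fell at or below zero."""


class ExactFitWarning(UserWarning):
    pass


@dataclass(frozen=True)
class CalibrationPoint:
    """(disorder, pediatric ADR %, reported prevalence %)."""

    label: str
    adr: float
    prevalence: float

    def __post_init__(self) -> None:
        if self.adr < 0:
            raise ValueError(f"{self.label}: ADR must be >= 0")
        if self.prevalence <= 0:
            raise ValueError(f"{self.label}: prevalence must be > 0")


@dataclass(frozen=True)
class CalibrationLine:
    """A prevalence-vs-ADR line on the percent scale (both axes)."""

    slope: float
    intercept: float
    r_squared: Optional[float] = None
    p_value: Optional[float] = None
    n: Optional[int] = None


#: Reference coefficients of the aneuploidy calibration (incidence vs ADR),
#: as conventionally quoted at 4 decimals.  Refitting the panel reproduces
#: them; they are provided for use as fixed inputs to extrapolation.
ANEUPLOIDY_REFERENCE_LINE = CalibrationLine(
    slope=0.0343, intercept=0.0045, r_squared=0.9987, p_value=0.00065, n=4
)

#: Reference coefficients of the genomic-disorder calibration (prevalence vs
#: ADR over the five-syndrome panel).  The exact (ADR, prevalence) pairs
#: behind these published coefficients are under-determined by the reported
#: prevalence ranges, so downstream extrapolations treat this line as a fixed
#: input rather than refitting it; see the methods note.
GENOMIC_DISORDER_REFERENCE_LINE = CalibrationLine(
    slope=0.0348, intercept=0.0039, r_squared=0.8758, p_value=0.019, n=5
)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A point prevalence estimate with its reciprocal 1-in-N rendering."""

    label: str
    prevalence_percent: float

    @property
    def one_in_n(self) -> int:
        return int(round(100.0 / self.prevalence_percent))

    def rendered(self, ndigits: int = 3) -> str:
        value = round_half_up(self.prevalence_percent, ndigits)
        return f"{value:.{ndigits}f}% (1/{int(round(100.0 / value)):,})"


class PrevalenceCalibration:
    """OLS calibration model of prevalence (%) against ADR (%).

    Parameters
    ----------
    adr, prevalence : array-like
        Calibration points on the percent scale.  At least two points with
        non-degenerate ADR variance are required to fit.
    labels : sequence of str, optional
        Disorder names, for the summary table.
    """

    def __init__(
        self,
        adr: Iterable[float],
        prevalence: Iterable[float],
        labels: Optional[Sequence[str]] = None,
    ):
        self.adr = np.asarray(list(adr), dtype=float)
        self.prevalence = np.asarray(list(prevalence), dtype=float)
        if self.adr.shape != self.prevalence.shape or self.adr.ndim != 1:
            raise ValueError("adr and prevalence must be 1-d and the same length")
        if self.adr.size < 2:
            raise ValueError("need at least two calibration points")
        if np.ptp(self.adr) == 0:
            raise ValueError("degenerate calibration: all ADR values equal")
        self.labels = list(labels) if labels is not None else [
            f"point{i}" for i in range(self.adr.size)
        ]

    @classmethod
    def from_points(cls, points: Sequence[CalibrationPoint]) -> "PrevalenceCalibration":
        return cls(
            adr=[p.adr for p in points],
            prevalence=[p.prevalence for p in points],
            labels=[p.label for p in points],
        )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        adr_col: str = "adr",
        prevalence_col: str = "prevalence",
        label_col: Optional[str] = "label",
    ) -> "PrevalenceCalibration":
        labels = (
            list(data[label_col]) if label_col and label_col in data.columns else None
        )
        return cls(data[adr_col], data[prevalence_col], labels)

    def fit(self) -> "PrevalenceCalibrationResults":
        """Closed-form OLS fit; returns the results object."""
        x, y = self.adr, self.prevalence
        n = x.size
        x_mean, y_mean = x.mean(), y.mean()
        sxx = float(((x - x_mean) ** 2).sum())
        sxy = float(((x - x_mean) * (y - y_mean)).sum())
        syy = float(((y - y_mean) ** 2).sum())
        slope = sxy / sxx
        intercept = y_mean - slope * x_mean
        fitted = intercept + slope * x
        resid = y - fitted
        ss_res = float((resid**2).sum())
        r_squared = 1.0 if syy == 0 else max(0.0, 1.0 - ss_res / syy)
        if n > 2:
            sigma2 = ss_res / (n - 2)
            se_slope = math.sqrt(sigma2 / sxx)
            se_intercept = math.sqrt(sigma2 * (1.0 / n + x_mean**2 / sxx))
            p_value = slope_p_from_r2(min(r_squared, 1.0), n)
        else:
            se_slope = se_intercept = float("nan")
            p_value = float("nan")  # flagged: a two-point line has no test
        return PrevalenceCalibrationResults(
            model=self,
            slope=slope,
            intercept=intercept,
            r_squared=r_squared,
            p_value=p_value,
            se_slope=se_slope,
            se_intercept=se_intercept,
            residuals=resid,
            fitted=fitted,
        )


@dataclass
class PrevalenceCalibrationResults:
    """Fit results: estimates, uncertainties, diagnostics, prediction."""

    model: PrevalenceCalibration
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    se_slope: float
    se_intercept: float
    residuals: np.ndarray
    fitted: np.ndarray

    @property
    def n(self) -> int:
        return self.model.adr.size

    @property
    def params(self) -> pd.Series:
        return pd.Series({"slope": self.slope, "intercept": self.intercept})

    @property
    def bse(self) -> pd.Series:
        return pd.Series({"slope": self.se_slope, "intercept": self.se_intercept})

    def as_line(self, ndigits: Optional[int] = 4) -> CalibrationLine:
        """Coefficients as a :class:`CalibrationLine`.

        ``ndigits`` rounds the coefficients as they would be quoted (the
        convention used when a published line is applied downstream); pass
        ``None`` for full precision.
        """
        slope, intercept = self.slope, self.intercept
        if ndigits is not None:
            slope = round_half_up(slope, ndigits)
            intercept = round_half_up(intercept, ndigits)
        return CalibrationLine(
            slope=slope,
            intercept=intercept,
            r_squared=self.r_squared,
            p_value=self.p_value,
            n=self.n,
        )

    def predict(self, adr: Union[float, Iterable[float]]) -> np.ndarray:
        values = np.atleast_1d(np.asarray(adr, dtype=float))
        return self.intercept + self.slope * values

    def summary(self) -> str:
        lines = [
            "Prevalence calibration (OLS, percent scale)",
            "=" * 47,
            f"n points        : {self.n}",
            f"slope           : {self.slope:.6f}  (se {self.se_slope:.6f})",
            f"intercept       : {self.intercept:.6f}  (se {self.se_intercept:.6f})",
            f"R-squared       : {self.r_squared:.4f}",
            f"slope p-value   : {self.p_value:.3g}",
            "-" * 47,
            f"{'disorder':<28}{'ADR%':>8}{'prev%':>10}",
        ]
        for label, x, y in zip(self.model.labels, self.model.adr, self.model.prevalence):
            lines.append(f"{label:<28}{x:>8.2f}{y:>10.4f}")
        return "\n".join(lines)


def slope_p_from_r2(r_squared: float, n: int) -> float:
    """Two-sided p-value of the zero-slope test from R-squared alone.

    Uses t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.  An exact fit
    (r^2 == 1) returns 0.0.
    """
    if not 0 <= r_squared <= 1:
        raise ValueError("r_squared must be in [0, 1]")
    if n < 3:
        raise ValueError("p-value requires at least 3 points")
    if r_squared == 1.0:
        return 0.0
    t = math.sqrt(r_squared) * math.sqrt((n - 2) / (1.0 - r_squared))
    return 2.0 * float(stats.t.sf(t, n - 2))


def predict_prevalence(
    line: CalibrationLine, adr: float, label: str = ""
) -> PrevalenceEstimate:
    """Extrapolate a prevalence from a calibration line.

    A non-positive prediction raises :class:`OutOfRangeError`: the line is
    only trusted inside the calibrated ADR range.
    """
    if adr < 0:
        raise ValueError("ADR must be >= 0")
    prevalence = line.slope * adr + line.intercept
    if prevalence <= 0:
        raise OutOfRangeError(
            f"extrapolation at ADR {adr}% predicts non-positive prevalence "
            f"({prevalence:.4g}%)"
        )
    return PrevalenceEstimate(label=label, prevalence_percent=prevalence)


# --------------------------------------------------------------------------
# building calibration panels from spectrum tables
# --------------------------------------------------------------------------

#: Aneuploidy panel: (spectrum row key, catalog label).
_ANEUPLOIDY_PANEL = [
    ("trisomy21", "trisomy21"),
    ("monosomy_x", "monosomy_x"),
    ("trisomy18", "trisomy18"),
    ("trisomy13", "trisomy13"),
]

#: Genomic-disorder panel: (catalog label, locus key, dosage rows summed for
#: the ADR numerator).  Deletion ADRs count cases carrying a deletion at the
#: locus, i.e. del plus del&dup rows.
_SYNDROME_PANEL = [
    ("dgs_vcfs", "22q11.21"),
    ("wbs", "7q11.23"),
    ("pws_as", "15q11-q13"),
    ("sms", "17p11.2"),
    ("hnpp", "17p12"),
]


def deletion_adr_count(pcnv_spectrum: SpectrumTable, locus: str) -> int:
    """Cases carrying a deletion at a locus: the del row plus any del&dup row."""
    count = 0
    for suffix in ("_del", "_del_and_dup"):
        try:
            count += pcnv_spectrum.entry(f"{locus}{suffix}").count
        except KeyError:
            pass
    return count


def _resolve_range(value: Union[float, tuple[float, float]], policy: str) -> float:
    if not isinstance(value, tuple):
        return float(value)
    lo, hi = value
    if policy == "midpoint":
        return (lo + hi) / 2.0
    if policy == "low":
        return lo
    if policy == "high":
        return hi
    raise ValueError(f"unknown range policy {policy!r}")


def build_calibration_sets(
    chromosomal_spectrum: SpectrumTable,
    pcnv_spectrum: SpectrumTable,
    catalog: Optional[pd.DataFrame] = None,
    range_policy: str = "midpoint",
    adr_ndigits: Optional[int] = 2,
) -> tuple[list[CalibrationPoint], list[CalibrationPoint]]:
    """Assemble the two calibration panels from pediatric spectrum tables.

    ADRs enter at their 2-decimal table rendering by default (the convention
    under which the reference coefficients were derived); pass
    ``adr_ndigits=None`` for full precision.  Reported prevalence ranges are
    resolved by ``range_policy`` (midpoint default).
    """
    if chromosomal_spectrum.setting is not Setting.PEDIATRIC:
        raise ValueError("calibration uses the pediatric-setting spectra")
    catalog = catalog if catalog is not None else load_incidence_catalog()

    def rounded(value: float) -> float:
        return value if adr_ndigits is None else round_half_up(value, adr_ndigits)

    aneuploidy = []
    cal_aneu = catalog[catalog["context"] == "calibration_aneuploidy"]
    for row_key, label in _ANEUPLOIDY_PANEL:
        match = cal_aneu[cal_aneu["label"] == label]
        if match.empty:
            raise KeyError(f"incidence catalog lacks calibration entry {label!r}")
        adr_value = rounded(chromosomal_spectrum.entry(row_key).adr)
        aneuploidy.append(
            CalibrationPoint(
                label=label, adr=adr_value, prevalence=float(match["value"].iloc[0])
            )
        )

    syndromes = []
    cal_syn = catalog[catalog["context"] == "calibration_syndrome"]
    for label, locus in _SYNDROME_PANEL:
        match = cal_syn[cal_syn["label"] == label]
        if match.empty:
            raise KeyError(f"incidence catalog lacks calibration entry {label!r}")
        count = deletion_adr_count(pcnv_spectrum, locus)
        adr_value = rounded(100.0 * count / pcnv_spectrum.denominator)
        syndromes.append(
            CalibrationPoint(
                label=label,
                adr=adr_value,
                prevalence=_resolve_range(match["value"].iloc[0], range_policy),
            )
        )
    return aneuploidy, syndromes
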