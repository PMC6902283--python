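"""Synthetic cohorts with known ground truth.

The generator emulates the data-generating process behind a two-setting
diagnostic series: each case draws an underlying abnormality (or none) from a
configurable incidence spectrum, a test combination from the setting's
assignment mix, and a detection outcome per test from a sensitivity model.
Findings are emitted only when detected, as ISCN-subset strings for
chromosomal abnormalities or CNV interval descriptors for pCNVs — so every
downstream stage (parsing, classification, denominators, rates) runs on
synthetic data exactly as it would on real exports.

The default sensitivity structure is the qualitative resolution model of the
three assays: karyotyping sees chromosomal abnormalities but no
submicroscopic CNVs; aCGH sees every dosage imbalance (including pCNVs) but
no balanced rearrangement; an aneuploidy FISH panel sees only the common
aneuploidies of chromosomes X, Y, 13, 18 and 21; targeted FISH sees only its
configured loci.  True per-assay sensitivities are not part of the reference
conditions, so the defaults are structural zeros and ones with config hooks.

``reference_cohort`` is different: a deterministic, non-random cohort whose
test-combination census, classified counts and denominators reproduce the
bundled reference spectrum tables exactly.  It is the golden input used to
validate the whole pipeline against the published summary statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .classify import classify_cohort
from .cohort import (
    CaseRecord,
    FishPurpose,
    Setting,
    TestModality,
    compute_denominators,
    default_test_census,
)
from .rates import build_chromosomal_spectrum, build_pcnv_spectrum
from .taxonomy import (
    AbnormalityCategory,
    CategoryGroup,
    CnvDescriptor,
    Dosage,
    Finding,
    GenomeBuild,
    RecurrentLocusTable,
    default_genome_build,
    default_locus_table,
)
from ._spectra_data import load_reference_spectra

__all__ = [
    "DetectionModel",
    "SimulationSpec",
    "GroundTruthLedger",
    "generate_cohort",
    "reference_cohort",
    "recovery_report",
    "expected_adr",
    "default_incidence",
    "default_test_mix",
]


# --------------------------------------------------------------------------
# abnormality tokens
# --------------------------------------------------------------------------

_FISH_ANEUPLOIDY_LEAVES = frozenset(
    {
        AbnormalityCategory.XXY,
        AbnormalityCategory.XYY,
        AbnormalityCategory.OTHER_MALE_SCA,
        AbnormalityCategory.MONOSOMY_X,
        AbnormalityCategory.XXX,
        AbnormalityCategory.OTHER_FEMALE_SCA,
        AbnormalityCategory.TRISOMY_21,
        AbnormalityCategory.TRISOMY_18,
        AbnormalityCategory.TRISOMY_13,
    }
)

_ISCN_TEMPLATES: dict[AbnormalityCategory, tuple[str, ...]] = {
    AbnormalityCategory.XXY: ("47,XXY",),
    AbnormalityCategory.XYY: ("47,XYY",),
    AbnormalityCategory.OTHER_MALE_SCA: ("48,XXYY",),
    AbnormalityCategory.MONOSOMY_X: ("45,X",),
    AbnormalityCategory.XXX: ("47,XXX",),
    AbnormalityCategory.OTHER_FEMALE_SCA: ("48,XXXX",),
    AbnormalityCategory.TRISOMY_21: ("47,XX,+21", "47,XY,+21"),
    AbnormalityCategory.TRISOMY_18: ("47,XX,+18", "47,XY,+18"),
    AbnormalityCategory.TRISOMY_13: ("47,XX,+13", "47,XY,+13"),
    AbnormalityCategory.OTHER_AUTOSOMAL_ANEUPLOIDY: ("47,XX,+8", "47,XY,+22"),
    AbnormalityCategory.TRIPLOIDY: ("69,XXX", "69,XXY"),
    AbnormalityCategory.TETRAPLOIDY: ("92,XXXX",),
    AbnormalityCategory.ROBERTSONIAN_BALANCED: (
        "45,XX,rob(13;14)(q10;q10)",
        "45,XY,rob(14;21)(q10;q10)",
    ),
    AbnormalityCategory.OTHER_BALANCED: (
        "46,XX,t(2;7)(p13;q22)",
        "46,XY,inv(9)(p12q13)",
    ),
    AbnormalityCategory.UNBALANCED_REARRANGEMENT: (
        "46,XX,del(5)(p14)",
        "47,XY,+mar",
    ),
}


@dataclass(frozen=True)
class _Token:
    """Parsed abnormality token."""

    kind: str  # "chrom" | "recurrent" | "subtelomeric" | "interstitial"
    leaf: Optional[AbnormalityCategory] = None
    locus: Optional[str] = None
    dosage: Optional[Dosage] = None

    @property
    def sensitivity_class(self) -> str:
        if self.kind != "chrom":
            return "pcnv"
        assert self.leaf is not None
        if self.leaf.group is CategoryGroup.NUMERICAL:
            return "numerical"
        if self.leaf is AbnormalityCategory.UNBALANCED_REARRANGEMENT:
            return "unbalanced"
        return "balanced"


def _parse_token(token: str) -> _Token:
    parts = token.split(":")
    if parts[0] == "recurrent":
        if len(parts) != 3:
            raise ValueError(f"recurrent token {token!r} must be recurrent:<locus>:<del|dup>")
        return _Token(kind="recurrent", locus=parts[1], dosage=Dosage(parts[2]))
    if parts[0] in ("subtelomeric", "interstitial"):
        dosage = Dosage(parts[1]) if len(parts) > 1 else Dosage.DELETION
        return _Token(kind=parts[0], dosage=dosage)
    leaf = AbnormalityCategory(token)
    if leaf.group is CategoryGroup.PCNV:
        raise ValueError(
            f"pCNV leaves need a qualified token (got {token!r}); use "
            "recurrent:<locus>:<dosage>, subtelomeric:<dosage> or interstitial:<dosage>"
        )
    return _Token(kind="chrom", leaf=leaf)


@dataclass(frozen=True)
class DetectionModel:
    """Per-assay detection probabilities by abnormality class.

    Classes: ``numerical``, ``balanced``, ``unbalanced`` (chromosomal-scale)
    and ``pcnv``.  The aneuploidy FISH panel is leaf-restricted rather than
    class-restricted; targeted FISH is locus-restricted (``None`` = every
    locus in the configured table).
    """

    karyotype: dict[str, float] = field(
        default_factory=lambda: {
            "numerical": 1.0,
            "balanced": 1.0,
            "unbalanced": 1.0,
            "pcnv": 0.0,
        }
    )
    acgh: dict[str, float] = field(
        default_factory=lambda: {
            "numerical": 1.0,
            "balanced": 0.0,
            "unbalanced": 1.0,
            "pcnv": 1.0,
        }
    )
    fish_aneuploidy_sensitivity: float = 1.0
    fish_targeted_sensitivity: float = 1.0
    fish_targeted_loci: Optional[frozenset[str]] = None  # None = all loci

    def probability(
        self, modality: TestModality, purpose: FishPurpose, token: _Token
    ) -> float:
        if modality is TestModality.KARYOTYPE:
            return self.karyotype[token.sensitivity_class]
        if modality is TestModality.ACGH:
            return self.acgh[token.sensitivity_class]
        if purpose is FishPurpose.ANEUPLOIDY_PANEL:
            if token.kind == "chrom" and token.leaf in _FISH_ANEUPLOIDY_LEAVES:
                return self.fish_aneuploidy_sensitivity
            return 0.0
        if purpose is FishPurpose.TARGETED_MICRODELETION:
            if token.kind == "recurrent" and (
                self.fish_targeted_loci is None or token.locus in self.fish_targeted_loci
            ):
                return self.fish_targeted_sensitivity
            return 0.0
        return 0.0

    def case_probability(
        self, tests: Iterable[TestModality], purpose: FishPurpose, token: _Token
    ) -> float:
        miss = 1.0
        for test in tests:
            miss *= 1.0 - self.probability(test, purpose, token)
        return 1.0 - miss


def default_test_mix(
    setting: Setting,
) -> list[tuple[frozenset[TestModality], FishPurpose, float]]:
    """Test-assignment probabilities proportional to the reference census."""
    census = default_test_census()
    census = census[census["setting"] == setting.value]
    total = census["count"].sum()
    mix = []
    for _, row in census.iterrows():
        tests = frozenset(TestModality(t) for t in row["tests"].split("|"))
        mix.append((tests, FishPurpose(row["fish_purpose"]), row["count"] / total))
    return mix


def default_incidence(setting: Setting) -> dict[str, float]:
    """Abnormality incidence spectrum matching the reference cohort's rates.

    Chromosomal leaf rates are referenced to the chromosomal composite
    denominator and pCNV rates to the pCNV denominator, which is what the
    composite-ADR estimator targets under the structural sensitivity model.
    """
    chrom_ref, pcnv_ref, denoms = load_reference_spectra()
    chrom_den = denoms[setting]["chromosomal"]
    pcnv_den = denoms[setting]["pcnv"]
    col = "prenatal_count" if setting is Setting.PRENATAL else "pediatric_count"

    spectrum: dict[str, float] = {}
    leaf_rows = chrom_ref[chrom_ref["kind"] == "leaf"]
    for _, row in leaf_rows.iterrows():
        count = int(row[col])
        if count == 0:
            continue
        token = "triploidy" if row["row"] == "polyploidy" else row["row"]
        token = {
            "xxy": "XXY",
            "xyy": "XYY",
            "monosomy_x": "monosomy_X",
            "xxx": "XXX",
        }.get(token, token)
        spectrum[token] = count / chrom_den

    for _, row in pcnv_ref.iterrows():
        count = int(row[col])
        if count == 0:
            continue
        if row["dosage"] in ("del", "dup"):
            spectrum[f"recurrent:{row['locus']}:{row['dosage']}"] = count / pcnv_den
        elif row["dosage"] == "del_and_dup":
            key = f"recurrent:{row['locus']}:del"
            spectrum[key] = spectrum.get(key, 0.0) + count / pcnv_den
        elif row["row"] == "subtelomeric":
            spectrum["subtelomeric:del"] = count / pcnv_den
        elif row["row"] == "interstitial":
            spectrum["interstitial:del"] = count / pcnv_den
    return spectrum


@dataclass
class SimulationSpec:
    """Conditions of one setting's synthetic cohort.

    Defaults reproduce the reference study's conditions: cohort sizes of
    3,608 (prenatal) and 4,509 (pediatric), the reference test-assignment
    census, the reference abnormality spectrum, and the structural 0/1
    sensitivity model.
    """

    setting: Setting
    n_cases: int
    years: tuple[int, ...] = tuple(range(2008, 2018))
    year_weights: Optional[tuple[float, ...]] = None
    test_mix: Optional[list[tuple[frozenset[TestModality], FishPurpose, float]]] = None
    incidence: Optional[dict[str, float]] = None
    detection: DetectionModel = field(default_factory=DetectionModel)
    multi_abnormality_prob: float = 0.001
    seed: int = 0

    @classmethod
    def prenatal_default(cls, seed: int = 0, n_cases: int = 3608) -> "SimulationSpec":
        return cls(setting=Setting.PRENATAL, n_cases=n_cases, seed=seed)

    @classmethod
    def pediatric_default(cls, seed: int = 0, n_cases: int = 4509) -> "SimulationSpec":
        return cls(setting=Setting.PEDIATRIC, n_cases=n_cases, seed=seed)

    def resolved(self) -> "SimulationSpec":
        spec = replace(
            self,
            test_mix=self.test_mix or default_test_mix(self.setting),
            incidence=self.incidence
            if self.incidence is not None
            else default_incidence(self.setting),
            year_weights=self.year_weights or tuple([1 / len(self.years)] * len(self.years)),
        )
        spec.validate()
        return spec

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        assert self.incidence is not None and self.test_mix is not None
        total = sum(self.incidence.values())
        if total >= 1.0:
            raise ValueError(
                f"incidence spectrum sums to {total:.3f}; must leave a normal remainder"
            )
        if any(p < 0 for p in self.incidence.values()):
            raise ValueError("incidence probabilities must be non-negative")
        for token in self.incidence:
            _parse_token(token)
        mix_total = sum(p for _, _, p in self.test_mix)
        if not np.isclose(mix_total, 1.0):
            raise ValueError(f"test mix probabilities sum to {mix_total}, expected 1")


@dataclass
class GroundTruthLedger:
    """Per-case truth emitted alongside a synthetic cohort."""

    frame: pd.DataFrame  # case_id, setting, year, true_token, tests, detected

    def abnormal(self) -> pd.DataFrame:
        return self.frame[self.frame["true_token"] != ""]


def _sample_cnv(
    rng: np.random.Generator,
    token: _Token,
    loci: RecurrentLocusTable,
    build: GenomeBuild,
) -> CnvDescriptor:
    """Sample coordinates in the region class the token names.

    Recurrent CNVs sit exactly on the locus interval.  Subtelomeric CNVs are
    uniform inside a terminal window; interstitial CNVs are uniform between
    the windows with log-uniform sizes of 0.1-5 Mb, rejecting draws that
    happen to reach a recurrent locus at the assignment threshold.
    """
    assert token.dosage is not None
    if token.kind == "recurrent":
        locus = loci.get(token.locus)
        return CnvDescriptor(
            locus.chromosome, locus.start, locus.end, token.dosage
        )
    from .classify import classify_cnv  # local import to avoid cycles

    target = (
        AbnormalityCategory.SUBTELOMERIC_PCNV
        if token.kind == "subtelomeric"
        else AbnormalityCategory.INTERSTITIAL_PCNV
    )
    chromosomes = [str(c) for c in range(1, 23)]
    for _ in range(200):
        chrom = chromosomes[rng.integers(len(chromosomes))]
        length = build.length(chrom)
        window = build.terminal_window_bp(chrom)
        size = int(round(10 ** rng.uniform(5, np.log10(5e6))))
        if token.kind == "subtelomeric":
            arm_start = length - window + 1 if rng.random() < 0.5 else 1
            lo = arm_start
            hi = min(arm_start + window - size, length - size)
        else:
            lo = window + 1
            hi = length - window - size
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi + 1))
        cnv = CnvDescriptor(chrom, start, start + size - 1, token.dosage)
        if classify_cnv(cnv, loci, build) is target:
            return cnv
    raise RuntimeError(f"could not place a {token.kind} CNV after 200 draws")


def _render_finding(
    rng: np.random.Generator,
    token: _Token,
    loci: RecurrentLocusTable,
    build: GenomeBuild,
) -> Finding:
    if token.kind == "chrom":
        assert token.leaf is not None
        templates = _ISCN_TEMPLATES[token.leaf]
        return Finding(karyotype=templates[rng.integers(len(templates))])
    return Finding(cnv=_sample_cnv(rng, token, loci, build))


def generate_cohort(
    specs: Union[SimulationSpec, Sequence[SimulationSpec]],
    loci: Optional[RecurrentLocusTable] = None,
    build: Optional[GenomeBuild] = None,
) -> tuple[list[CaseRecord], GroundTruthLedger]:
    """Draw a synthetic cohort (one or both settings) with its truth ledger.

    Reproducible: the same spec (including seed) yields an identical cohort.
    """
    if isinstance(specs, SimulationSpec):
        specs = [specs]
    loci = loci if loci is not None else default_locus_table()
    build = build if build is not None else default_genome_build()
    cases: list[CaseRecord] = []
    truth_rows: list[dict] = []
    for spec in specs:
        spec = spec.resolved()
        rng = np.random.default_rng(spec.seed)
        assert spec.incidence is not None and spec.test_mix is not None
        tokens = list(spec.incidence.keys())
        probs = np.array([spec.incidence[t] for t in tokens])
        normal_prob = 1.0 - probs.sum()
        choices = tokens + ["__normal__"]
        choice_probs = np.append(probs, normal_prob)
        mix_probs = np.array([p for _, _, p in spec.test_mix])
        mix_probs = mix_probs / mix_probs.sum()
        prefix = "PRE" if spec.setting is Setting.PRENATAL else "PED"
        for i in range(spec.n_cases):
            year = int(rng.choice(spec.years, p=spec.year_weights))
            mix_idx = int(rng.choice(len(spec.test_mix), p=mix_probs))
            tests, purpose, _ = spec.test_mix[mix_idx]
            drawn = [str(rng.choice(choices, p=choice_probs))]
            if drawn[0] != "__normal__" and rng.random() < spec.multi_abnormality_prob:
                second = str(rng.choice(choices, p=choice_probs))
                if second != "__normal__" and second != drawn[0]:
                    drawn.append(second)
            findings: list[Finding] = []
            truth_tokens: list[str] = []
            detected_flags: list[bool] = []
            for raw in drawn:
                if raw == "__normal__":
                    continue
                token = _parse_token(raw)
                detected = any(
                    rng.random() < spec.detection.probability(test, purpose, token)
                    for test in sorted(tests, key=lambda t: t.value)
                )
                truth_tokens.append(raw)
                detected_flags.append(detected)
                if detected:
                    findings.append(_render_finding(rng, token, loci, build))
            case = CaseRecord(
                case_id=f"{prefix}-{spec.seed}-{i:05d}",
                setting=spec.setting,
                year=year,
                tests=tests,
                fish_purpose=purpose,
                findings=tuple(findings),
            )
            cases.append(case)
            truth_rows.append(
                {
                    "case_id": case.case_id,
                    "setting": spec.setting.value,
                    "year": year,
                    "true_token": ";".join(truth_tokens),
                    "tests": "|".join(sorted(t.value for t in tests)),
                    "detected": any(detected_flags),
                    "n_abnormalities": len(truth_tokens),
                    "n_detected": sum(detected_flags),
                }
            )
    ledger = GroundTruthLedger(
        frame=pd.DataFrame(
            truth_rows,
            columns=[
                "case_id",
                "setting",
                "year",
                "true_token",
                "tests",
                "detected",
                "n_abnormalities",
                "n_detected",
            ],
        )
    )
    return cases, ledger


def expected_adr(spec: SimulationSpec, token_str: str, spectrum: str) -> float:
    """The identifiable target of a composite ADR under a simulation spec.

    For an abnormality with incidence p, the ADR measured on the spectrum's
    composite denominator targets
    ``p * sum_c w_c e_c d_c / sum_c w_c e_c`` where w_c are the assignment
    weights, e_c flags denominator eligibility of combination c and d_c is
    the probability at least one test in c detects the abnormality.
    """
    spec = spec.resolved()
    assert spec.incidence is not None and spec.test_mix is not None
    token = _parse_token(token_str)
    p = spec.incidence.get(token_str, 0.0)
    num = den = 0.0
    for tests, purpose, weight in spec.test_mix:
        fish_only = tests == frozenset({TestModality.FISH})
        if spectrum == "chromosomal":
            eligible = bool(tests & {TestModality.KARYOTYPE, TestModality.ACGH}) or (
                fish_only and purpose is FishPurpose.ANEUPLOIDY_PANEL
            )
        elif spectrum == "pcnv":
            eligible = TestModality.ACGH in tests or (
                fish_only and purpose is FishPurpose.TARGETED_MICRODELETION
            )
        else:
            raise ValueError("spectrum must be 'chromosomal' or 'pcnv'")
        if not eligible:
            continue
        den += weight
        num += weight * spec.detection.case_probability(tests, purpose, token)
    if den == 0:
        return 0.0
    return 100.0 * p * num / den


def recovery_report(
    specs: Union[SimulationSpec, Sequence[SimulationSpec]],
    replicates: int = 3,
    tokens: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Run the full pipeline on replicate cohorts and compare estimated ADRs
    with their identifiable targets.

    Replicates reseed independently from the spec's seed.  The report has one
    row per (setting, token): the target ADR, mean estimate, deviation, and
    the Monte-Carlo standard error of the mean.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if isinstance(specs, SimulationSpec):
        specs = [specs]
    rows = []
    for spec in specs:
        spec = spec.resolved()
        assert spec.incidence is not None
        use_tokens = list(tokens) if tokens is not None else list(spec.incidence)
        estimates: dict[str, list[float]] = {t: [] for t in use_tokens}
        for rep in range(replicates):
            rep_spec = replace(spec, seed=spec.seed + 7919 * rep)
            cases, _ = generate_cohort(rep_spec)
            classifications = classify_cohort(cases)
            denoms = compute_denominators(cases, spec.setting)
            chrom = build_chromosomal_spectrum(cases, classifications, denoms)
            pcnv = build_pcnv_spectrum(cases, classifications, denoms)
            for token_str in use_tokens:
                token = _parse_token(token_str)
                if token.kind == "chrom":
                    count = sum(
                        1
                        for case, cls in zip(cases, classifications)
                        if case.chromosomal_eligible and token.leaf in cls.categories
                    )
                    denom = denoms.chromosomal
                else:
                    if token.kind == "recurrent":
                        count = sum(
                            1
                            for case, cls in zip(cases, classifications)
                            if case.pcnv_eligible
                            and (token.locus, token.dosage) in cls.locus_hits
                        )
                    else:
                        target_leaf = (
                            AbnormalityCategory.SUBTELOMERIC_PCNV
                            if token.kind == "subtelomeric"
                            else AbnormalityCategory.INTERSTITIAL_PCNV
                        )
                        count = sum(
                            1
                            for case, cls in zip(cases, classifications)
                            if case.pcnv_eligible and target_leaf in cls.categories
                        )
                    denom = denoms.pcnv
                estimates[token_str].append(100.0 * count / denom if denom else 0.0)
        for token_str in use_tokens:
            token = _parse_token(token_str)
            spectrum = "chromosomal" if token.kind == "chrom" else "pcnv"
            target = expected_adr(spec, token_str, spectrum)
            values = np.array(estimates[token_str])
            rows.append(
                {
                    "setting": spec.setting.value,
                    "token": token_str,
                    "target_adr": target,
                    "mean_estimate": float(values.mean()),
                    "deviation": float(values.mean() - target),
                    "mc_se": float(values.std(ddof=1) / np.sqrt(replicates))
                    if replicates > 1
                    else float("nan"),
                    "replicates": replicates,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# the deterministic reference cohort
# --------------------------------------------------------------------------

_SUBTEL_SITES = [
    ("2", 240_000_001, 242_500_000),
    ("6", 168_500_001, 170_500_000),
    ("10", 133_000_001, 135_000_000),
    ("12", 131_500_001, 133_500_000),
]
_INTERSTITIAL_SITES = [
    ("6", 100_000_001, 101_200_000),
    ("10", 60_000_001, 61_000_000),
    ("12", 50_000_001, 50_800_000),
    ("9", 30_000_001, 31_100_000),
]


def _polyploidy_split(count: int) -> list[str]:
    # mostly triploid with a tetraploid minority, as seen in practice
    n_tetra = count // 5
    return ["69,XXX"] * (count - n_tetra) + ["92,XXXX"] * n_tetra


def reference_cohort() -> tuple[list[CaseRecord], GroundTruthLedger]:
    """Deterministic cohort reproducing the bundled reference tables.

    Builds the exact test-combination census of the reference series, then
    assigns abnormal findings so that classification recovers every count of
    the chromosomal and pCNV reference spectra: chromosomal abnormalities are
    placed on karyotyped cases, pCNVs on aCGH-tested cases.  No randomness is
    involved; calling twice yields identical cohorts.
    """
    chrom_ref, pcnv_ref, _ = load_reference_spectra()
    loci = default_locus_table()
    census = default_test_census()
    years = itertools.cycle(range(2008, 2018))

    cases: list[CaseRecord] = []
    truth_rows: list[dict] = []
    for setting in (Setting.PRENATAL, Setting.PEDIATRIC):
        col = "prenatal_count" if setting is Setting.PRENATAL else "pediatric_count"
        prefix = "PRE" if setting is Setting.PRENATAL else "PED"

        # ---- findings to place ------------------------------------------
        chrom_findings: list[tuple[str, Finding]] = []
        for _, row in chrom_ref[chrom_ref["kind"] == "leaf"].iterrows():
            count = int(row[col])
            if count == 0:
                continue
            key = row["row"]
            if key == "polyploidy":
                karyotypes = _polyploidy_split(count)
            else:
                leaf = {
                    "xxy": AbnormalityCategory.XXY,
                    "xyy": AbnormalityCategory.XYY,
                    "monosomy_x": AbnormalityCategory.MONOSOMY_X,
                    "xxx": AbnormalityCategory.XXX,
                }.get(key) or AbnormalityCategory(key)
                templates = _ISCN_TEMPLATES[leaf]
                karyotypes = [templates[i % len(templates)] for i in range(count)]
            chrom_findings.extend((key, Finding(karyotype=k)) for k in karyotypes)

        pcnv_findings: list[tuple[str, tuple[Finding, ...]]] = []
        sub_cycle = itertools.cycle(_SUBTEL_SITES)
        int_cycle = itertools.cycle(_INTERSTITIAL_SITES)
        dosage_cycle = itertools.cycle([Dosage.DELETION, Dosage.DUPLICATION])
        for _, row in pcnv_ref.iterrows():
            count = int(row[col])
            if count == 0:
                continue
            if row["dosage"] in ("del", "dup"):
                locus = loci.get(row["locus"])
                cnv = CnvDescriptor(
                    locus.chromosome, locus.start, locus.end, Dosage(row["dosage"])
                )
                pcnv_findings.extend(
                    (row["row"], (Finding(cnv=cnv),)) for _ in range(count)
                )
            elif row["dosage"] == "del_and_dup":
                locus = loci.get(row["locus"])
                pair = tuple(
                    Finding(
                        cnv=CnvDescriptor(
                            locus.chromosome, locus.start, locus.end, dosage
                        )
                    )
                    for dosage in (Dosage.DELETION, Dosage.DUPLICATION)
                )
                pcnv_findings.extend((row["row"], pair) for _ in range(count))
            elif row["row"] == "subtelomeric":
                for _ in range(count):
                    chrom, start, end = next(sub_cycle)
                    cnv = CnvDescriptor(chrom, start, end, next(dosage_cycle))
                    pcnv_findings.append((row["row"], (Finding(cnv=cnv),)))
            elif row["row"] == "interstitial":
                for _ in range(count):
                    chrom, start, end = next(int_cycle)
                    cnv = CnvDescriptor(chrom, start, end, next(dosage_cycle))
                    pcnv_findings.append((row["row"], (Finding(cnv=cnv),)))

        # ---- build the census and attach findings -----------------------
        setting_census = census[census["setting"] == setting.value]
        counter = itertools.count()
        chrom_iter = iter(chrom_findings)
        pcnv_iter = iter(pcnv_findings)
        chrom_left = len(chrom_findings)
        pcnv_left = len(pcnv_findings)
        for _, crow in setting_census.iterrows():
            tests = frozenset(TestModality(t) for t in crow["tests"].split("|"))
            purpose = FishPurpose(crow["fish_purpose"])
            karyotyped = TestModality.KARYOTYPE in tests
            acgh = TestModality.ACGH in tests
            for _ in range(int(crow["count"])):
                idx = next(counter)
                findings: tuple[Finding, ...] = ()
                token = ""
                if chrom_left and karyotyped and not acgh:
                    token, finding = next(chrom_iter)
                    findings = (finding,)
                    chrom_left -= 1
                elif pcnv_left and acgh:
                    token, group = next(pcnv_iter)
                    findings = group
                    pcnv_left -= 1
                case = CaseRecord(
                    case_id=f"{prefix}-{idx:05d}",
                    setting=setting,
                    year=next(years),
                    tests=tests,
                    fish_purpose=purpose,
                    findings=findings,
                )
                cases.append(case)
                truth_rows.append(
                    {
                        "case_id": case.case_id,
                        "setting": setting.value,
                        "year": case.year,
                        "true_token": token,
                        "tests": crow["tests"],
                        "detected": bool(findings),
                        "n_abnormalities": 1 if token else 0,
                        "n_detected": int(bool(findings)),
                    }
                )
        if chrom_left or pcnv_left:
            raise RuntimeError(
                f"{setting.value}: could not place all reference findings "
                f"({chrom_left} chromosomal, {pcnv_left} pCNV left)"
            )
    ledger = GroundTruthLedger(frame=pd.DataFrame(truth_rows))
    return cases, ledger
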