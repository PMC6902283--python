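"""Classification of findings into the abnormality taxonomy.

Karyotype strings are parsed from an ISCN subset covering the abnormality
classes that appear in diagnostic spectrum tables: modal number, sex
complement, whole-chromosome gains/losses, and del/dup/t/rob/inv/i/r/add/der
/mar events, including mosaic forms written ``clone1/clone2``.

CNV intervals are classified by a fixed decision order:

1. span above the chromosomal-scale bound (default 10 Mb) → unbalanced
   rearrangement (karyotype-visible scale);
2. reciprocal overlap with a recurrent genomic-disorder locus at or above the
   configured fraction (default 0.5) → recurrent genomic disorder;
3. overlap with a terminal window of the chromosome → subtelomeric pCNV;
4. otherwise → interstitial pCNV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .cohort import CaseRecord
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

__all__ = [
    "ParseError",
    "UnclassifiableError",
    "Event",
    "Clone",
    "KaryotypeDescriptor",
    "ClassifierConfig",
    "CaseClassification",
    "parse_iscn_subset",
    "classify_karyotype",
    "classify_cnv",
    "classify_finding",
    "classify_case",
    "classify_cohort",
]


class ParseError(ValueError):
    """Karyotype string not covered by the supported ISCN subset."""

    def __init__(self, message: str, span: str = ""):
        super().__init__(message)
        self.span = span


class UnclassifiableError(ValueError):
    """A finding that parsed but maps to no taxonomy leaf.

    Raised rather than silently returning "normal": an unrecognized
    abnormality must never deflate a detection rate.
    """


@dataclass(frozen=True)
class Event:
    """One rearrangement token, e.g. ``del(5)(p14)`` or ``+21``."""

    kind: str  # gain|loss|del|dup|t|rob|inv|i|r|add|der|mar
    target: str = ""  # chromosome(s) involved, as written
    bands: str = ""  # breakpoint argument list, as written


@dataclass(frozen=True)
class Clone:
    modal: int
    sex: str
    events: tuple[Event, ...] = ()

    @property
    def is_normal(self) -> bool:
        return self.modal == 46 and self.sex in ("XX", "XY") and not self.events


@dataclass(frozen=True)
class KaryotypeDescriptor:
    clones: tuple[Clone, ...]
    source: str = ""


_EVENT_SIMPLE = re.compile(r"^(del|dup|inv|add|i|r)\((\d+|X|Y)\)(\([^)]*\))?$")
_EVENT_MULTI = re.compile(r"^(t|rob|der)\(([0-9XY;]+)\)((?:\([^)]*\))*)$")
_GAIN = re.compile(r"^\+(\d+|mar|X|Y)$")
_LOSS = re.compile(r"^-(\d+|X|Y)$")
_SEX = re.compile(r"^[XY]+$")


def _split_top_level(text: str) -> list[str]:
    """Split on commas not enclosed in parentheses."""
    parts, depth, buf = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append("".join(buf).strip())
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf).strip())
    return parts


def _parse_clone(text: str) -> Clone:
    fields = _split_top_level(text)
    if len(fields) < 2:
        raise ParseError(f"clone {text!r} lacks a modal number and sex field", text)
    try:
        modal = int(fields[0].lstrip("mos ").strip())
    except ValueError:
        raise ParseError(f"modal number {fields[0]!r} is not an integer", fields[0])
    sex = fields[1].strip()
    if not _SEX.match(sex):
        raise ParseError(f"sex complement {sex!r} not recognized", sex)
    events = []
    for token in fields[2:]:
        if not token:
            continue
        if m := _GAIN.match(token):
            kind = "mar" if m.group(1) == "mar" else "gain"
            events.append(Event(kind, m.group(1)))
        elif m := _LOSS.match(token):
            events.append(Event("loss", m.group(1)))
        elif m := _EVENT_SIMPLE.match(token):
            events.append(Event(m.group(1), m.group(2), m.group(3) or ""))
        elif m := _EVENT_MULTI.match(token):
            events.append(Event(m.group(1), m.group(2), m.group(3) or ""))
        else:
            raise ParseError(f"unrecognized event token {token!r}", token)
    return Clone(modal=modal, sex=sex, events=tuple(events))


def parse_iscn_subset(karyotype: str) -> KaryotypeDescriptor:
    """Parse an ISCN-subset karyotype string.

    Mosaic karyotypes written ``a/b`` yield one clone per component.  An
    empty string or an unsupported token raises :class:`ParseError` carrying
    the offending span.
    """
    text = karyotype.strip()
    if not text:
        raise ParseError("empty karyotype string")
    clones = tuple(_parse_clone(part) for part in text.split("/"))
    return KaryotypeDescriptor(clones=clones, source=karyotype)


_SEX_LEAVES = {
    "XXY": AbnormalityCategory.XXY,
    "XYY": AbnormalityCategory.XYY,
    "X": AbnormalityCategory.MONOSOMY_X,
    "XXX": AbnormalityCategory.XXX,
}

_TRISOMY_LEAVES = {
    "21": AbnormalityCategory.TRISOMY_21,
    "18": AbnormalityCategory.TRISOMY_18,
    "13": AbnormalityCategory.TRISOMY_13,
}

_UNBALANCED_KINDS = {"del", "dup", "add", "i", "r", "mar", "der", "loss"}
_BALANCED_KINDS = {"t", "inv"}


def _classify_clone(clone: Clone) -> Optional[AbnormalityCategory]:
    if clone.is_normal:
        return None
    # polyploidy first: a 69,XXX complement is triploid, not a sex aneuploidy
    if clone.modal == 69:
        return AbnormalityCategory.TRIPLOIDY
    if clone.modal == 92:
        return AbnormalityCategory.TETRAPLOIDY

    autosome_gains = [e for e in clone.events if e.kind == "gain" and e.target.isdigit()]
    autosome_losses = [e for e in clone.events if e.kind == "loss" and e.target.isdigit()]
    sex_gain_loss = [
        e for e in clone.events if e.kind in ("gain", "loss") and e.target in ("X", "Y")
    ]

    # autosomal aneuploidy outranks sex-chromosome aneuploidy and structure
    for event in autosome_gains:
        if event.target in _TRISOMY_LEAVES:
            return _TRISOMY_LEAVES[event.target]
    if autosome_gains or autosome_losses:
        return AbnormalityCategory.OTHER_AUTOSOMAL_ANEUPLOIDY

    # sex-chromosome complement, folding in any ±X/±Y tokens
    sex = clone.sex
    for event in sex_gain_loss:
        if event.kind == "gain":
            sex += event.target
        else:
            sex = sex.replace(event.target, "", 1)
    sex = "".join(sorted(sex))  # canonical order: X before Y
    if sex not in ("XX", "XY"):
        leaf = _SEX_LEAVES.get(sex)
        if leaf is not None:
            return leaf
        if "Y" in sex:
            return AbnormalityCategory.OTHER_MALE_SCA
        return AbnormalityCategory.OTHER_FEMALE_SCA

    structural = [e for e in clone.events if e.kind not in ("gain", "loss")]
    if not structural:
        raise UnclassifiableError(
            f"clone {clone.modal},{clone.sex} has modal {clone.modal} but no "
            "classifiable abnormality"
        )
    if any(e.kind in _UNBALANCED_KINDS for e in structural):
        return AbnormalityCategory.UNBALANCED_REARRANGEMENT
    if any(e.kind == "rob" for e in structural):
        # a carried Robertsonian fusion is balanced at modal 45
        if clone.modal == 45:
            return AbnormalityCategory.ROBERTSONIAN_BALANCED
        return AbnormalityCategory.UNBALANCED_REARRANGEMENT
    if any(e.kind in _BALANCED_KINDS for e in structural):
        return AbnormalityCategory.OTHER_BALANCED
    raise UnclassifiableError(
        f"no classification rule for events {[e.kind for e in structural]}"
    )


def classify_karyotype(
    descriptor: KaryotypeDescriptor,
) -> Optional[AbnormalityCategory]:
    """Map a parsed karyotype to a taxonomy leaf, or ``None`` if normal.

    Mosaics are classified by the first abnormal clone; the mosaic fraction is
    ignored.  Aneuploidies outrank structural events within a clone.
    """
    for clone in descriptor.clones:
        leaf = _classify_clone(clone)
        if leaf is not None:
            return leaf
    return None


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def classify_cnv(
    cnv: CnvDescriptor,
    loci: Optional[RecurrentLocusTable] = None,
    build: Optional[GenomeBuild] = None,
    size_threshold_mb: float = 10.0,
    min_reciprocal_overlap: float = 0.5,
    terminal_policy: str = "any_overlap",
) -> AbnormalityCategory:
    """Classify a pathogenic CNV interval (see module docstring for the
    decision order).

    ``terminal_policy`` is ``"any_overlap"`` (default) or ``"containment"``:
    whether touching a terminal window suffices or the CNV must lie entirely
    within it.
    """
    if not cnv.pathogenic:
        raise ValueError("benign/VUS calls must be filtered before classification")
    loci = loci if loci is not None else default_locus_table()
    build = build if build is not None else default_genome_build()
    chrom_len = build.length(cnv.chromosome)
    if cnv.end > chrom_len:
        raise ValueError(
            f"CNV {cnv.chromosome}:{cnv.start}-{cnv.end} exceeds chromosome "
            f"length {chrom_len}"
        )
    if cnv.span_mb > size_threshold_mb:
        return AbnormalityCategory.UNBALANCED_REARRANGEMENT

    if match_locus(cnv, loci, min_reciprocal_overlap) is not None:
        return AbnormalityCategory.RECURRENT_GENOMIC_DISORDER

    window = build.terminal_window_bp(cnv.chromosome)
    p_ter = (1, window)
    q_ter = (chrom_len - window + 1, chrom_len)
    if terminal_policy == "any_overlap":
        terminal = any(
            _overlap(cnv.start, cnv.end, lo, hi) > 0 for lo, hi in (p_ter, q_ter)
        )
    elif terminal_policy == "containment":
        terminal = any(
            lo <= cnv.start and cnv.end <= hi for lo, hi in (p_ter, q_ter)
        )
    else:
        raise ValueError(f"unknown terminal_policy {terminal_policy!r}")
    if terminal:
        return AbnormalityCategory.SUBTELOMERIC_PCNV
    return AbnormalityCategory.INTERSTITIAL_PCNV


def match_locus(
    cnv: CnvDescriptor,
    loci: RecurrentLocusTable,
    min_reciprocal_overlap: float = 0.5,
):
    """Return the recurrent locus the CNV maps to, or ``None``.

    Locus assignment uses reciprocal overlap — the shared span must cover at
    least the threshold fraction of *both* the CNV and the locus — and is
    independent of dosage: a deletion and a duplication on the same interval
    resolve to the same locus.
    """
    best = None
    best_frac = 0.0
    for locus in loci:
        if locus.chromosome != cnv.chromosome:
            continue
        shared = _overlap(cnv.start, cnv.end, locus.start, locus.end)
        if shared == 0:
            continue
        frac = min(shared / cnv.span, shared / locus.span)
        if frac >= min_reciprocal_overlap and frac > best_frac:
            best, best_frac = locus, frac
    return best


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable classification thresholds (defaults reproduce the reference
    pipeline; see the methods note for the rationale behind each)."""

    size_threshold_mb: float = 10.0
    min_reciprocal_overlap: float = 0.5
    terminal_policy: str = "any_overlap"
    # case-level primary-class precedence, highest first
    precedence: tuple[CategoryGroup, ...] = (
        CategoryGroup.NUMERICAL,
        CategoryGroup.STRUCTURAL,
        CategoryGroup.PCNV,
    )


DEFAULT_CONFIG = ClassifierConfig()


def classify_finding(
    finding: Finding,
    loci: Optional[RecurrentLocusTable] = None,
    build: Optional[GenomeBuild] = None,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> Optional[AbnormalityCategory]:
    """Classify a single finding; ``None`` means a normal karyotype string."""
    if finding.precoded is not None:
        return finding.precoded
    if finding.karyotype is not None:
        return classify_karyotype(parse_iscn_subset(finding.karyotype))
    assert finding.cnv is not None
    return classify_cnv(
        finding.cnv,
        loci,
        build,
        size_threshold_mb=config.size_threshold_mb,
        min_reciprocal_overlap=config.min_reciprocal_overlap,
        terminal_policy=config.terminal_policy,
    )


@dataclass
class CaseClassification:
    """Per-case classification summary.

    ``primary`` is the single leaf used when a case must be counted once
    (chosen by the configured group precedence); the ADR numerators instead
    use the two booleans, so a case with both a chromosomal abnormality and a
    pCNV increments both spectra.
    """

    case_id: str
    categories: tuple[AbnormalityCategory, ...]
    primary: Optional[AbnormalityCategory]
    locus_hits: tuple[tuple[str, Dosage], ...] = ()

    @property
    def chromosomal_abnormal(self) -> bool:
        return any(
            c.group in (CategoryGroup.NUMERICAL, CategoryGroup.STRUCTURAL)
            for c in self.categories
        )

    @property
    def pcnv_abnormal(self) -> bool:
        return any(c.group is CategoryGroup.PCNV for c in self.categories)


def classify_case(
    record: CaseRecord,
    loci: Optional[RecurrentLocusTable] = None,
    build: Optional[GenomeBuild] = None,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> CaseClassification:
    """Classify every finding on a case and derive the case-level summary."""
    loci = loci if loci is not None else default_locus_table()
    build = build if build is not None else default_genome_build()
    categories: list[AbnormalityCategory] = []
    locus_hits: list[tuple[str, Dosage]] = []
    for finding in record.findings:
        try:
            leaf = classify_finding(finding, loci, build, config)
        except (ParseError, UnclassifiableError, ValueError) as exc:
            raise type(exc)(f"case {record.case_id}: {exc}") from exc
        if leaf is None:
            continue
        categories.append(leaf)
        if (
            leaf is AbnormalityCategory.RECURRENT_GENOMIC_DISORDER
            and finding.cnv is not None
        ):
            locus = match_locus(finding.cnv, loci, config.min_reciprocal_overlap)
            assert locus is not None
            locus_hits.append((locus.label, finding.cnv.dosage))
    primary = None
    for group in config.precedence:
        in_group = [c for c in categories if c.group is group]
        if in_group:
            primary = in_group[0]
            break
    return CaseClassification(
        case_id=record.case_id,
        categories=tuple(categories),
        primary=primary,
        locus_hits=tuple(locus_hits),
    )


def classify_cohort(
    cases: Sequence[CaseRecord],
    loci: Optional[RecurrentLocusTable] = None,
    build: Optional[GenomeBuild] = None,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> list[CaseClassification]:
    loci = loci if loci is not None else default_locus_table()
    build = build if build is not None else default_genome_build()
    return [classify_case(case, loci, build, config) for case in cases]
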