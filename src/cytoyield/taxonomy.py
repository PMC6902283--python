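"""Domain types shared across the pipeline.

The abnormality taxonomy has two major branches — chromosomal abnormalities
(numerical and structural, detectable at karyotype resolution) and pathogenic
copy number variants (pCNVs, submicroscopic imbalances detectable by
microarray or targeted FISH).  Every classified finding maps to exactly one
leaf of this tree.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Iterator, Optional

__all__ = [
    "AbnormalityCategory",
    "CategoryGroup",
    "CnvDescriptor",
    "Dosage",
    "Finding",
    "GenomeBuild",
    "RecurrentLocus",
    "RecurrentLocusTable",
    "default_genome_build",
    "default_locus_table",
]


class CategoryGroup(str, Enum):
    """Major branch of the abnormality taxonomy."""

    NUMERICAL = "numerical"
    STRUCTURAL = "structural"
    PCNV = "pcnv"


class AbnormalityCategory(str, Enum):
    """Leaf of the abnormality taxonomy.

    The leaf set mirrors the rows of the diagnostic-spectrum tables: sex
    chromosome aneuploidies, autosomal aneuploidies, polyploidies, balanced
    and unbalanced structural rearrangements, and the three pCNV classes.
    """

    XXY = "XXY"
    XYY = "XYY"
    OTHER_MALE_SCA = "other_male_sca"
    MONOSOMY_X = "monosomy_X"
    XXX = "XXX"
    OTHER_FEMALE_SCA = "other_female_sca"
    TRISOMY_21 = "trisomy21"
    TRISOMY_18 = "trisomy18"
    TRISOMY_13 = "trisomy13"
    OTHER_AUTOSOMAL_ANEUPLOIDY = "other_autosomal_aneuploidy"
    TRIPLOIDY = "triploidy"
    TETRAPLOIDY = "tetraploidy"
    ROBERTSONIAN_BALANCED = "robertsonian_balanced"
    OTHER_BALANCED = "other_balanced"
    UNBALANCED_REARRANGEMENT = "unbalanced_rearrangement"
    RECURRENT_GENOMIC_DISORDER = "recurrent_genomic_disorder"
    SUBTELOMERIC_PCNV = "subtelomeric_pcnv"
    INTERSTITIAL_PCNV = "interstitial_pcnv"

    @property
    def group(self) -> CategoryGroup:
        return _LEAF_GROUP[self]


_NUMERICAL = {
    AbnormalityCategory.XXY,
    AbnormalityCategory.XYY,
    AbnormalityCategory.OTHER_MALE_SCA,
    AbnormalityCategory.MONOSOMY_X,
    AbnormalityCategory.XXX,
    AbnormalityCategory.OTHER_FEMALE_SCA,
    AbnormalityCategory.TRISOMY_21,
    AbnormalityCategory.TRISOMY_18,
    AbnormalityCategory.TRISOMY_13,
    AbnormalityCategory.OTHER_AUTOSOMAL_ANEUPLOIDY,
    AbnormalityCategory.TRIPLOIDY,
    AbnormalityCategory.TETRAPLOIDY,
}
_STRUCTURAL = {
    AbnormalityCategory.ROBERTSONIAN_BALANCED,
    AbnormalityCategory.OTHER_BALANCED,
    AbnormalityCategory.UNBALANCED_REARRANGEMENT,
}
_PCNV = {
    AbnormalityCategory.RECURRENT_GENOMIC_DISORDER,
    AbnormalityCategory.SUBTELOMERIC_PCNV,
    AbnormalityCategory.INTERSTITIAL_PCNV,
}

_LEAF_GROUP: dict[AbnormalityCategory, CategoryGroup] = {}
for _leaf in AbnormalityCategory:
    if _leaf in _NUMERICAL:
        _LEAF_GROUP[_leaf] = CategoryGroup.NUMERICAL
    elif _leaf in _STRUCTURAL:
        _LEAF_GROUP[_leaf] = CategoryGroup.STRUCTURAL
    else:
        assert _leaf in _PCNV
        _LEAF_GROUP[_leaf] = CategoryGroup.PCNV


class Dosage(str, Enum):
    DELETION = "del"
    DUPLICATION = "dup"


VALID_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


@dataclass(frozen=True)
class CnvDescriptor:
    """A copy-number interval on a GRCh37-style build.

    Coordinates are 1-based and the interval is closed, matching clinical
    reporting conventions.  ``pathogenic`` is an input: variant interpretation
    happens upstream and benign/VUS calls never enter the yield statistics.
    """

    chromosome: str
    start: int
    end: int
    dosage: Dosage
    pathogenic: bool = True

    def __post_init__(self) -> None:
        if self.chromosome not in VALID_CHROMOSOMES:
            raise ValueError(f"unknown chromosome label {self.chromosome!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}"
            )

    @property
    def span(self) -> int:
        """Interval length in base pairs (closed interval)."""
        return self.end - self.start + 1

    @property
    def span_mb(self) -> float:
        return self.span / 1e6

    def token(self) -> str:
        """Serialize to the delimited-file finding token."""
        flag = "" if self.pathogenic else ":benign_or_vus"
        return f"cnv:{self.dosage.value}:{self.chromosome}:{self.start}-{self.end}{flag}"

    @classmethod
    def from_token(cls, token: str) -> "CnvDescriptor":
        parts = token.split(":")
        if len(parts) not in (4, 5) or parts[0] != "cnv":
            raise ValueError(f"malformed CNV token {token!r}")
        _, dosage, chrom, interval = parts[:4]
        pathogenic = len(parts) == 4 or parts[4] != "benign_or_vus"
        try:
            start_s, end_s = interval.split("-")
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"malformed CNV interval in {token!r}") from exc
        return cls(chrom, start, end, Dosage(dosage), pathogenic)


@dataclass(frozen=True)
class Finding:
    """One abnormal result on a case.

    Exactly one representation is populated: an ISCN-subset karyotype string,
    a CNV interval descriptor, or a pre-coded taxonomy leaf (for findings
    classified outside this pipeline, e.g. targeted-FISH calls reported only
    by syndrome name).
    """

    karyotype: Optional[str] = None
    cnv: Optional[CnvDescriptor] = None
    precoded: Optional[AbnormalityCategory] = None

    def __post_init__(self) -> None:
        populated = sum(x is not None for x in (self.karyotype, self.cnv, self.precoded))
        if populated != 1:
            raise ValueError(
                "a Finding must populate exactly one of karyotype/cnv/precoded"
            )

    def token(self) -> str:
        if self.karyotype is not None:
            return f"kt:{self.karyotype}"
        if self.cnv is not None:
            return self.cnv.token()
        assert self.precoded is not None
        return f"cat:{self.precoded.value}"

    @classmethod
    def from_token(cls, token: str) -> "Finding":
        if token.startswith("kt:"):
            return cls(karyotype=token[3:])
        if token.startswith("cnv:"):
            return cls(cnv=CnvDescriptor.from_token(token))
        if token.startswith("cat:"):
            return cls(precoded=AbnormalityCategory(token[4:]))
        # bare tokens beginning with a modal number are accepted as karyotypes
        if token[:1].isdigit():
            return cls(karyotype=token)
        raise ValueError(f"unrecognized finding token {token!r}")


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths plus the terminal-window sizes used to call a CNV
    subtelomeric.

    The windows default to the upper bounds of the conventional ranges:
    15 Mb for the large autosomes 1–12 and 10 Mb for the small autosomes
    13–22.  Sex chromosomes use the large-chromosome window.
    """

    lengths: dict[str, int]
    large_window_mb: float = 15.0
    small_window_mb: float = 10.0

    def __post_init__(self) -> None:
        if self.large_window_mb <= 0 or self.small_window_mb <= 0:
            raise ValueError("terminal windows must be positive")
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    def length(self, chromosome: str) -> int:
        try:
            return self.lengths[chromosome]
        except KeyError:
            raise KeyError(f"chromosome {chromosome!r} not in build") from None

    def terminal_window_bp(self, chromosome: str) -> int:
        small = chromosome.isdigit() and 13 <= int(chromosome) <= 22
        mb = self.small_window_mb if small else self.large_window_mb
        return int(round(mb * 1e6))


@dataclass(frozen=True)
class RecurrentLocus:
    label: str
    chromosome: str
    start: int
    end: int
    deletion_syndrome: str = ""
    duplication_syndrome: str = ""

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class RecurrentLocusTable:
    """The recurrent genomic-disorder loci a CNV can be assigned to.

    Intervals must not overlap within a chromosome so that a CNV resolves to
    at most one locus at the reciprocal-overlap threshold.
    """

    loci: list[RecurrentLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[RecurrentLocus]] = {}
        for locus in self.loci:
            by_chrom.setdefault(locus.chromosome, []).append(locus)
        for chrom, group in by_chrom.items():
            group = sorted(group, key=lambda l: l.start)
            for a, b in zip(group, group[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping loci on chromosome {chrom}: "
                        f"{a.label} and {b.label}"
                    )

    def __iter__(self) -> Iterator[RecurrentLocus]:
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def get(self, label: str) -> RecurrentLocus:
        for locus in self.loci:
            if locus.label == label:
                return locus
        raise KeyError(f"no locus labelled {label!r}")

    def labels(self) -> list[str]:
        return [locus.label for locus in self.loci]


def _data_rows(name: str) -> Iterable[dict[str, str]]:
    path = resources.files("cytoyield.data").joinpath(name)
    with path.open("r", encoding="utf-8") as handle:
        lines = [ln for ln in handle if not ln.startswith("#")]
    return csv.DictReader(lines, delimiter="\t")


def default_genome_build(
    large_window_mb: float = 15.0, small_window_mb: float = 10.0
) -> GenomeBuild:
    """The GRCh37 build shipped with the package."""
    lengths = {
        row["chromosome"]: int(row["length"]) for row in _data_rows("grch37_lengths.tsv")
    }
    return GenomeBuild(lengths, large_window_mb, small_window_mb)


def default_locus_table() -> RecurrentLocusTable:
    """The recurrent-locus table shipped with the package (configuration
    defaults on GRCh37; see ``data/recurrent_loci.tsv`` to customize)."""
    loci = [
        RecurrentLocus(
            label=row["locus"],
            chromosome=row["chromosome"],
            start=int(row["start"]),
            end=int(row["end"]),
            deletion_syndrome=row["deletion_syndrome"],
            duplication_syndrome=row["duplication_syndrome"],
        )
        for row in _data_rows("recurrent_loci.tsv")
    ]
    return RecurrentLocusTable(loci)
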