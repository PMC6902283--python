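"""Classification: ISCN parsing, karyotype and CNV leaf assignment."""

from __future__ import annotations

import numpy as np
import pytest

from cytoyield.classify import (
    ClassifierConfig,
    ParseError,
    UnclassifiableError,
    classify_case,
    classify_cnv,
    classify_karyotype,
    match_locus,
    parse_iscn_subset,
)
from cytoyield.cohort import CaseRecord, FishPurpose, Setting, TestModality
from cytoyield.taxonomy import (
    AbnormalityCategory as C,
    CnvDescriptor,
    Dosage,
    Finding,
    default_genome_build,
    default_locus_table,
)

LOCI = default_locus_table()
BUILD = default_genome_build()


class TestParser:
    def test_trisomy_string(self):
        desc = parse_iscn_subset("47,XX,+21")
        (clone,) = desc.clones
        assert clone.modal == 47 and clone.sex == "XX"
        assert [(e.kind, e.target) for e in clone.events] == [("gain", "21")]

    def test_monosomy_x(self):
        (clone,) = parse_iscn_subset("45,X").clones
        assert (clone.modal, clone.sex, clone.events) == (45, "X", ())

    def test_translocation_breakpoints_kept(self):
        (clone,) = parse_iscn_subset("46,XY,t(2;7)(p13;q22)").clones
        (event,) = clone.events
        assert event.kind == "t" and event.target == "2;7" and "(p13;q22)" in event.bands

    def test_mosaic_yields_clone_list(self):
        desc = parse_iscn_subset("45,X/46,XX")
        assert [c.modal for c in desc.clones] == [45, 46]

    def test_empty_string_rejected(self):
        with pytest.raises(ParseError):
            parse_iscn_subset("  ")

    def test_unrecognized_token_carries_span(self):
        with pytest.raises(ParseError) as err:
            parse_iscn_subset("46,XX,qdp(3)(q21)")
        assert "qdp" in str(err.value)


KARYOTYPE_CASES = [
    ("47,XXY", C.XXY),
    ("47,XYY", C.XYY),
    ("48,XXYY", C.OTHER_MALE_SCA),
    ("45,X", C.MONOSOMY_X),
    ("47,XXX", C.XXX),
    ("48,XXXX", C.OTHER_FEMALE_SCA),
    ("47,XX,+21", C.TRISOMY_21),
    ("47,XY,+18", C.TRISOMY_18),
    ("47,XX,+13", C.TRISOMY_13),
    ("47,XY,+8", C.OTHER_AUTOSOMAL_ANEUPLOIDY),
    ("69,XXX", C.TRIPLOIDY),
    ("69,XXY", C.TRIPLOIDY),
    ("92,XXXX", C.TETRAPLOIDY),
    ("45,XX,rob(14;21)(q10;q10)", C.ROBERTSONIAN_BALANCED),
    ("45,XY,rob(13;14)(q10;q10)", C.ROBERTSONIAN_BALANCED),
    ("46,XX,t(2;7)(p13;q22)", C.OTHER_BALANCED),
    ("46,XY,inv(9)(p12q13)", C.OTHER_BALANCED),
    ("46,XX,del(5)(p14)", C.UNBALANCED_REARRANGEMENT),
    ("46,XY,dup(1)(q21q31)", C.UNBALANCED_REARRANGEMENT),
    ("47,XY,+mar", C.UNBALANCED_REARRANGEMENT),
    ("46,XX,r(15)", C.UNBALANCED_REARRANGEMENT),
    ("45,X/46,XX", C.MONOSOMY_X),  # mosaic: abnormal clone decides
    ("46,XX", None),
    ("46,XY", None),
]


class TestKaryotypeClassification:
    @pytest.mark.parametrize("karyotype,expected", KARYOTYPE_CASES)
    def test_leaf_assignment(self, karyotype, expected):
        assert classify_karyotype(parse_iscn_subset(karyotype)) is expected

    def test_aneuploidy_outranks_structure(self):
        # translocation trisomy 21 counts as trisomy 21, not a rearrangement
        leaf = classify_karyotype(parse_iscn_subset("46,XX,+21,rob(14;21)(q10;q10)"))
        assert leaf is C.TRISOMY_21

    def test_abnormal_modal_without_events_is_unclassifiable(self):
        with pytest.raises(UnclassifiableError):
            classify_karyotype(parse_iscn_subset("45,XY"))


class TestCnvClassification:
    def test_recurrent_locus_by_reciprocal_overlap(self):
        cnv = CnvDescriptor("22", 18_900_000, 21_500_000, Dosage.DELETION)
        assert classify_cnv(cnv, LOCI, BUILD) is C.RECURRENT_GENOMIC_DISORDER
        assert match_locus(cnv, LOCI).label == "22q11.21"

    def test_subtelomeric_by_terminal_window(self):
        # chr2 length 243,199,373; the interval sits inside the last 15 Mb
        cnv = CnvDescriptor("2", 239_500_000, 242_000_000, Dosage.DUPLICATION)
        assert classify_cnv(cnv, LOCI, BUILD) is C.SUBTELOMERIC_PCNV

    def test_interstitial_far_from_everything(self):
        cnv = CnvDescriptor("2", 100_000_000, 101_000_000, Dosage.DELETION)
        assert classify_cnv(cnv, LOCI, BUILD) is C.INTERSTITIAL_PCNV

    def test_chromosomal_scale_cnv_is_unbalanced(self):
        cnv = CnvDescriptor("2", 100_000_000, 140_000_000, Dosage.DELETION)
        assert classify_cnv(cnv, LOCI, BUILD) is C.UNBALANCED_REARRANGEMENT

    def test_coordinates_beyond_build_rejected(self):
        cnv = CnvDescriptor("21", 1, 50_000_000, Dosage.DELETION)
        with pytest.raises(ValueError, match="exceeds chromosome length"):
            classify_cnv(cnv, LOCI, BUILD)

    def test_benign_rejected_upstream(self):
        cnv = CnvDescriptor("2", 1_000_000, 1_100_000, Dosage.DELETION, pathogenic=False)
        with pytest.raises(ValueError, match="filtered"):
            classify_cnv(cnv, LOCI, BUILD)

    def test_locus_assignment_is_dosage_invariant(self):
        for locus in LOCI:
            for dosage in Dosage:
                cnv = CnvDescriptor(locus.chromosome, locus.start, locus.end, dosage)
                hit = match_locus(cnv, LOCI)
                assert hit is not None and hit.label == locus.label

    def test_agrees_with_brute_force_oracle(self):
        """classify_cnv versus independent interval arithmetic on 1,000
        random CNVs: enumerate every locus and window intersection directly."""
        rng = np.random.default_rng(20241109)
        chromosomes = [str(i) for i in range(1, 23)] + ["X", "Y"]
        for _ in range(1000):
            chrom = chromosomes[rng.integers(len(chromosomes))]
            length = BUILD.length(chrom)
            size = int(rng.integers(50_000, 20_000_001))
            start = int(rng.integers(1, max(2, length - size)))
            cnv = CnvDescriptor(
                chrom, start, start + size - 1, Dosage.DELETION
            )

            # oracle: plain enumeration, no shared helpers
            if cnv.span / 1e6 > 10.0:
                expected = C.UNBALANCED_REARRANGEMENT
            else:
                hit = None
                for locus in LOCI:
                    if locus.chromosome != chrom:
                        continue
                    shared = min(cnv.end, locus.end) - max(cnv.start, locus.start) + 1
                    if shared <= 0:
                        continue
                    locus_span = locus.end - locus.start + 1
                    if shared / cnv.span >= 0.5 and shared / locus_span >= 0.5:
                        hit = locus
                if hit is not None:
                    expected = C.RECURRENT_GENOMIC_DISORDER
                else:
                    window = (
                        10_000_000 if chrom.isdigit() and int(chrom) >= 13 else 15_000_000
                    )
                    if cnv.start <= window or cnv.end >= length - window + 1:
                        expected = C.SUBTELOMERIC_PCNV
                    else:
                        expected = C.INTERSTITIAL_PCNV
            assert classify_cnv(cnv, LOCI, BUILD) is expected, cnv

    def test_every_pathogenic_cnv_gets_exactly_one_leaf(self):
        """Partition property: random valid CNVs always classify, to a single
        leaf of the taxonomy."""
        rng = np.random.default_rng(7)
        chromosomes = [str(i) for i in range(1, 23)] + ["X"]
        pcnv_leaves = {
            C.RECURRENT_GENOMIC_DISORDER,
            C.SUBTELOMERIC_PCNV,
            C.INTERSTITIAL_PCNV,
            C.UNBALANCED_REARRANGEMENT,
        }
        for _ in range(500):
            chrom = chromosomes[rng.integers(len(chromosomes))]
            length = BUILD.length(chrom)
            size = int(rng.integers(1_000, 30_000_001))
            start = int(rng.integers(1, max(2, length - size)))
            cnv = CnvDescriptor(chrom, start, start + size - 1, Dosage.DUPLICATION)
            assert classify_cnv(cnv, LOCI, BUILD) in pcnv_leaves


def _case(findings, case_id="c", tests=(TestModality.KARYOTYPE, TestModality.ACGH)):
    return CaseRecord(
        case_id, Setting.PEDIATRIC, 2012, frozenset(tests), FishPurpose.NONE, tuple(findings)
    )


class TestCaseClassification:
    def test_single_trisomy_case(self):
        cls = classify_case(_case([Finding(karyotype="47,XY,+21")]))
        assert cls.primary is C.TRISOMY_21
        assert cls.chromosomal_abnormal and not cls.pcnv_abnormal

    def test_single_recurrent_cnv_case(self):
        dgs = LOCI.get("22q11.21")
        cnv = CnvDescriptor(dgs.chromosome, dgs.start, dgs.end, Dosage.DELETION)
        cls = classify_case(_case([Finding(cnv=cnv)]))
        assert cls.primary is C.RECURRENT_GENOMIC_DISORDER
        assert cls.pcnv_abnormal and not cls.chromosomal_abnormal
        assert cls.locus_hits == (("22q11.21", Dosage.DELETION),)

    def test_precedence_and_double_counting(self):
        cnv = CnvDescriptor("2", 100_000_000, 101_000_000, Dosage.DELETION)
        cls = classify_case(_case([Finding(karyotype="45,X"), Finding(cnv=cnv)]))
        assert cls.primary is C.MONOSOMY_X  # numerical > pCNV
        assert cls.chromosomal_abnormal and cls.pcnv_abnormal

    def test_error_carries_case_id(self):
        with pytest.raises(ParseError, match="case weird-1"):
            classify_case(_case([Finding(karyotype="46,XX,zz(1)")], case_id="weird-1"))

    def test_precoded_finding_passes_through(self):
        cls = classify_case(_case([Finding(precoded=C.SUBTELOMERIC_PCNV)]))
        assert cls.primary is C.SUBTELOMERIC_PCNV

    def test_configurable_precedence(self):
        from cytoyield.taxonomy import CategoryGroup

        cnv = CnvDescriptor("2", 100_000_000, 101_000_000, Dosage.DELETION)
        config = ClassifierConfig(
            precedence=(CategoryGroup.PCNV, CategoryGroup.NUMERICAL, CategoryGroup.STRUCTURAL)
        )
        cls = classify_case(
            _case([Finding(karyotype="45,X"), Finding(cnv=cnv)]),
        )
        flipped = classify_case(
            _case([Finding(karyotype="45,X"), Finding(cnv=cnv)]), config=config
        )
        assert cls.primary is C.MONOSOMY_X
        assert flipped.primary is C.INTERSTITIAL_PCNV
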