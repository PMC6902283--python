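"""Cohort model: I/O round-trips, invariants, composite denominators."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoyield.cohort import (
    CaseRecord,
    CohortError,
    FishPurpose,
    SchemaError,
    Setting,
    StudyWindow,
    TestModality,
    annual_caseload,
    compute_denominators,
    inventory,
    read_cases,
    write_cases,
)
from cytoyield.taxonomy import Finding

K, A, F = TestModality.KARYOTYPE, TestModality.ACGH, TestModality.FISH


def make_case(case_id="c1", setting=Setting.PRENATAL, year=2010, tests=(K,),
              fish_purpose=FishPurpose.NONE, findings=()):
    return CaseRecord(case_id, setting, year, frozenset(tests), fish_purpose, findings)


# census of the reference prenatal/pediatric cohorts, as (tests, purpose, count)
PRENATAL_CENSUS = [
    ((K,), FishPurpose.NONE, 2269),
    ((K, A), FishPurpose.NONE, 781),
    ((K, F), FishPurpose.ANEUPLOIDY_PANEL, 331),
    ((K, A, F), FishPurpose.ANEUPLOIDY_PANEL, 185),
    ((A,), FishPurpose.NONE, 31),
    ((A, F), FishPurpose.ANEUPLOIDY_PANEL, 7),
    ((F,), FishPurpose.ANEUPLOIDY_PANEL, 4),
]
PEDIATRIC_CENSUS = [
    ((A,), FishPurpose.NONE, 1526),
    ((K, A), FishPurpose.NONE, 1401),
    ((K,), FishPurpose.NONE, 1091),
    ((K, F, A), FishPurpose.ANEUPLOIDY_PANEL, 194),
    ((K, F), FishPurpose.ANEUPLOIDY_PANEL, 133),
    ((A, F), FishPurpose.ANEUPLOIDY_PANEL, 89),
    ((F,), FishPurpose.ANEUPLOIDY_PANEL, 9),
    ((F,), FishPurpose.TARGETED_MICRODELETION, 66),
]


def census_cases(census, setting):
    cases = []
    for i, (tests, purpose, count) in enumerate(census):
        for j in range(count):
            cases.append(
                make_case(f"{setting.value}-{i}-{j}", setting, 2008 + j % 10, tests, purpose)
            )
    return cases


class TestValidation:
    def test_fish_purpose_requires_fish(self):
        case = make_case(tests=(K,), fish_purpose=FishPurpose.ANEUPLOIDY_PANEL)
        with pytest.raises(CohortError, match="FISH not among tests"):
            case.validate()

    def test_fish_without_purpose_rejected(self):
        case = make_case(tests=(F,), fish_purpose=FishPurpose.NONE)
        with pytest.raises(CohortError, match="fish_purpose"):
            case.validate()

    def test_empty_tests_rejected(self):
        with pytest.raises(CohortError, match="no tests"):
            make_case(tests=()).validate()

    def test_year_outside_window_rejected(self):
        case = make_case(year=2003)
        with pytest.raises(CohortError, match="outside study window"):
            case.validate()
        case.validate(StudyWindow(2000, 2005))  # configurable window accepts it


class TestIO:
    def test_round_trip_is_identity(self, tmp_path):
        cases = [
            make_case("p1", Setting.PRENATAL, 2010, (K,)),
            make_case("p2", Setting.PEDIATRIC, 2012, (A,),
                      findings=(Finding(karyotype="47,XX,+21"),)),
            make_case("p3", Setting.PEDIATRIC, 2015, (F,),
                      FishPurpose.ANEUPLOIDY_PANEL),
        ]
        path = tmp_path / "cases.csv"
        write_cases(cases, path)
        again = read_cases(path)
        assert again == cases
        # writer output is byte-stable
        write_cases(again, tmp_path / "cases2.csv")
        assert (tmp_path / "cases.csv").read_bytes() == (tmp_path / "cases2.csv").read_bytes()

    def test_multi_valued_tests_cell(self, tmp_path):
        path = tmp_path / "cases.csv"
        path.write_text(
            "case_id,setting,year,tests,fish_purpose,findings\n"
            "x,prenatal,2010,karyotype|acgh,none,\n"
        )
        (record,) = read_cases(path)
        assert record.tests == frozenset({K, A})

    def test_unknown_token_names_offender(self, tmp_path):
        path = tmp_path / "cases.csv"
        path.write_text(
            "case_id,setting,year,tests,fish_purpose,findings\n"
            "x,prenatal,2010,microscope,none,\n"
        )
        with pytest.raises(CohortError, match="microscope"):
            read_cases(path)

    def test_invariant_violation_reports_row(self, tmp_path):
        path = tmp_path / "cases.csv"
        path.write_text(
            "case_id,setting,year,tests,fish_purpose,findings\n"
            "x,prenatal,2010,karyotype,aneuploidy_panel,\n"
        )
        with pytest.raises(CohortError, match="row 1"):
            read_cases(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "cases.csv"
        path.write_text("case_id,setting,year\nx,prenatal,2010\n")
        with pytest.raises(SchemaError, match="tests"):
            read_cases(path)


class TestDenominators:
    def test_prenatal_census(self):
        cases = census_cases(PRENATAL_CENSUS, Setting.PRENATAL)
        denoms = compute_denominators(cases, Setting.PRENATAL)
        assert denoms.total == 3608
        assert denoms.chromosomal == 3608
        assert denoms.pcnv == 1004

    def test_pediatric_census(self):
        cases = census_cases(PEDIATRIC_CENSUS, Setting.PEDIATRIC)
        denoms = compute_denominators(cases, Setting.PEDIATRIC)
        assert denoms.total == 4509
        assert denoms.chromosomal == 4443
        assert denoms.pcnv == 3276

    def test_targeted_fish_only_case(self):
        case = make_case(tests=(F,), fish_purpose=FishPurpose.TARGETED_MICRODELETION)
        denoms = compute_denominators([case], Setting.PRENATAL)
        assert (denoms.chromosomal, denoms.pcnv) == (0, 1)

    def test_empty_cohort_gives_zeros(self):
        denoms = compute_denominators([], Setting.PRENATAL)
        assert (denoms.chromosomal, denoms.pcnv, denoms.total) == (0, 0, 0)

    def test_wrong_setting_rejected(self):
        case = make_case(setting=Setting.PEDIATRIC)
        with pytest.raises(CohortError):
            compute_denominators([case], Setting.PRENATAL)

    def test_partition_of_setting_total(self):
        """Chromosomal-eligible, targeted-FISH-only and 'neither' classes are
        disjoint and partition the cohort."""
        cases = census_cases(PEDIATRIC_CENSUS, Setting.PEDIATRIC)
        chrom = sum(c.chromosomal_eligible for c in cases)
        targeted_only = sum(
            c.fish_only and c.fish_purpose is FishPurpose.TARGETED_MICRODELETION
            for c in cases
        )
        neither = sum(
            not c.chromosomal_eligible
            and not (c.fish_only and c.fish_purpose is FishPurpose.TARGETED_MICRODELETION)
            for c in cases
        )
        assert chrom + targeted_only + neither == len(cases)
        assert neither == 0  # every reference combination qualifies somewhere

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.sampled_from(
                [(tests, purpose) for tests, purpose, _ in PEDIATRIC_CENSUS]
            ),
            max_size=30,
        )
    )
    def test_monotone_under_case_addition(self, combos):
        cases = [
            make_case(f"c{i}", Setting.PEDIATRIC, 2010, tests, purpose)
            for i, (tests, purpose) in enumerate(combos)
        ]
        prev_chrom = prev_pcnv = 0
        for i in range(len(cases) + 1):
            denoms = compute_denominators(cases[:i], Setting.PEDIATRIC)
            assert denoms.chromosomal >= prev_chrom
            assert denoms.pcnv >= prev_pcnv
            prev_chrom, prev_pcnv = denoms.chromosomal, denoms.pcnv


class TestInventory:
    def test_totals_match(self):
        cases = census_cases(PRENATAL_CENSUS, Setting.PRENATAL)
        inv = inventory(cases)
        assert inv.total(Setting.PRENATAL) == 3608
        assert sum(inv.counts.values()) == 3608

    def test_empty_inventory(self):
        inv = inventory([])
        assert inv.counts == {} and inv.totals == {}

    def test_duplicate_id_counted_but_flagged(self):
        cases = [make_case("dup"), make_case("dup")]
        with pytest.warns(UserWarning, match="dup"):
            inv = inventory(cases)
        assert inv.total(Setting.PRENATAL) == 2
        assert any("dup" in w for w in inv.warnings)


class TestAnnualCaseload:
    def test_multimodal_case_counts_once_in_total(self):
        case = make_case(tests=(K, A), year=2010)
        frame = annual_caseload([case])
        by_modality = dict(zip(frame["modality"], frame["count"]))
        assert by_modality == {"karyotype": 1, "acgh": 1, "total": 1}

    def test_empty_cohort_empty_table(self):
        assert annual_caseload([]).empty

    def test_declining_yearly_quota_recovered(self):
        # deterministic declining quotas stand in for the generator's per-year weights
        quotas = {2008 + i: 40 - 4 * i for i in range(10)}
        cases = [
            make_case(f"c{y}-{j}", year=y)
            for y, n in quotas.items()
            for j in range(n)
        ]
        frame = annual_caseload(cases)
        totals = frame[frame["modality"] == "total"].sort_values("year")["count"]
        assert list(totals) == sorted(totals, reverse=True)
        assert dict(zip(frame[frame["modality"] == "total"]["year"], totals)) == quotas
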