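"""Served-population arithmetic and the diagnostic-efficacy table."""

from __future__ import annotations

import numpy as np
import pytest

from cytoyield.cohort import Setting
from cytoyield.efficacy import (
    EfficacyBand,
    ServedPopulationModel,
    build_efficacy_table,
    detected_per_10k,
    ds_dgs_ratio,
    efficacy_band,
    efficacy_percent,
    estimate_coverage,
    expected_per_10k,
    render_ratio,
)

DEFAULTS = ServedPopulationModel()


class TestPer10k:
    def test_newborn_units_with_defaults(self):
        # 2,000,000 people * 1% birth rate * 10 years = 20 ten-thousands
        assert DEFAULTS.newborn_units == pytest.approx(20.0)

    @pytest.mark.parametrize(
        "count,expected", [(227, 11.35), (320, 16.0), (0, 0.0)]
    )
    def test_detected_examples(self, count, expected):
        assert detected_per_10k(count, DEFAULTS) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "one_in_n,expected", [(830, 12.048), (4000, 2.5), (10000, 1.0)]
    )
    def test_expected_examples(self, one_in_n, expected):
        assert expected_per_10k(1 / one_in_n) == pytest.approx(expected, abs=5e-4)

    def test_detected_linear_in_count_and_inverse_in_population(self):
        base = detected_per_10k(100, DEFAULTS)
        assert detected_per_10k(300, DEFAULTS) == pytest.approx(3 * base)
        doubled = ServedPopulationModel(population=4_000_000)
        assert detected_per_10k(100, doubled) == pytest.approx(base / 2)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            ServedPopulationModel(population=0)


class TestEfficacy:
    @pytest.mark.parametrize(
        "detected,expected,percent,band",
        [
            (11, 12, 92, EfficacyBand.HIGHLY_EFFECTIVE),
            (0.2, 2.5, 8, EfficacyBand.UNDER_DETECTION),
            (7.5, 12, 63, EfficacyBand.VARIABLE),
            (5, 5, 100, EfficacyBand.HIGHLY_EFFECTIVE),
        ],
    )
    def test_examples(self, detected, expected, percent, band):
        from cytoyield._render import round_half_up

        value = efficacy_percent(detected, expected)
        assert round_half_up(value, 0) == percent
        assert efficacy_band(value) is band

    def test_scale_invariance(self):
        assert efficacy_percent(3, 7) == pytest.approx(efficacy_percent(30, 70))

    def test_zero_expected_rejected(self):
        with pytest.raises(ZeroDivisionError):
            efficacy_percent(1, 0)


class TestDsDgsRatio:
    def test_reference_ratios(self):
        assert render_ratio(ds_dgs_ratio(227, 4)) == "57"
        assert render_ratio(ds_dgs_ratio(150, 46)) == "3.3"

    def test_equal_counts_give_one(self):
        assert ds_dgs_ratio(9, 9) == pytest.approx(1.0)
        assert render_ratio(1.0) == "1.0"

    def test_zero_dgs_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ds_dgs_ratio(5, 0)


class TestCoverage:
    def test_statewide_fractions(self):
        cov = estimate_coverage(38, 5, 36_000)
        assert cov.dgs_fraction == pytest.approx(5 / 9)
        # computed DS expectation is births/830 ~ 43.4/yr
        assert cov.statewide_expected_ds == pytest.approx(36_000 / 830)
        assert cov.ds_fraction == pytest.approx(38 / (36_000 / 830))
        lo, hi = cov.detection_fraction_range
        assert lo == pytest.approx(100 * 5 / 9)
        # with the externally quoted expectation of 45 DS newborns/yr the
        # upper end of the band lands at ~84%
        quoted = estimate_coverage(38, 5, 36_000, expected_overrides={"ds": 45})
        assert quoted.ds_fraction * 100 == pytest.approx(84.4, abs=0.1)
        assert quoted.implied_served_population == pytest.approx(0.6 * 3_600_000)

    def test_zero_detected_gives_zero_fractions(self):
        cov = estimate_coverage(0, 0, 36_000)
        assert cov.detection_fraction_range == (0.0, 0.0)

    def test_fractions_match_direct_division_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            ds, dgs = rng.uniform(1, 60, size=2)
            births = rng.uniform(10_000, 100_000)
            cov = estimate_coverage(ds, dgs, births)
            assert cov.ds_fraction == pytest.approx(ds / (births / 830))
            assert cov.dgs_fraction == pytest.approx(dgs / (births / 4000))


# expected cells of the reference efficacy table, keyed by row:
# (expected, pre_detected, pre_eff, ped_detected, ped_eff)
REFERENCE_TABLE = {
    "trisomy21": ("12", "11", "92%", "7.5", "63%"),
    "monosomy_x": ("2.5", "2.3", "92%", "1.2", "48%"),
    "xxy": ("10", "0.4", "4%", "1.4", "14%"),
    "xxx": ("11", "0.4", "4%", "0.4", "4%"),
    "xyy": ("10", "0.1", "1%", "0.3", "3%"),
    "robertsonian_balanced": ("9", "0.3", "3%", "0.2", "2%"),
    "all_chromosomal": ("64", "27", "42%", "18", "28%"),
    "dgs_vcfs": ("2.5", "0.2", "8%", "2.3", "92%"),
    "16p11.2_del": ("1.7", "", "", "0.75", "44%"),
    "1q21.1_del": ("1.4", "", "", "0.25", "18%"),
    "pws_as": ("1.25", "", "", "0.85", "68%"),
    "wbs": ("1", "", "", "0.4", "40%"),
    "recurrent_genomic_disorders": ("25", "0.85", "3%", "11.6", "46%"),
    "all_pcnv": ("33", "1.3", "4%", "16", "48%"),
    "total_cytogenomic": ("97", "28.3", "29%", "34", "35%"),
}


class TestEfficacyTable:
    def test_replication_reproduces_reference_cell_by_cell(self, reference_spectra):
        spectra = {
            s: (reference_spectra[s]["chromosomal"], reference_spectra[s]["pcnv"])
            for s in Setting
        }
        rows = build_efficacy_table(spectra, mode="replicate")
        by_key = {}
        for row in rows:
            by_key.setdefault(row.key, {})[row.setting] = row
        assert set(by_key) == set(REFERENCE_TABLE)
        for key, (exp, pre_det, pre_eff, ped_det, ped_eff) in REFERENCE_TABLE.items():
            pre = by_key[key][Setting.PRENATAL]
            ped = by_key[key][Setting.PEDIATRIC]
            assert pre.expected_rendered == exp, key
            if pre_det:
                assert pre.detected_rendered == pre_det, key
                assert pre.efficacy_rendered == pre_eff, key
            else:
                assert pre.detected_count == 0
            assert ped.detected_rendered == ped_det, key
            assert ped.efficacy_rendered == ped_eff, key

    def test_headline_totals_and_dgs(self, reference_spectra):
        spectra = {
            s: (reference_spectra[s]["chromosomal"], reference_spectra[s]["pcnv"])
            for s in Setting
        }
        rows = build_efficacy_table(spectra)
        totals = {r.setting: r for r in rows if r.key == "total_cytogenomic"}
        assert totals[Setting.PRENATAL].efficacy_rendered == "29%"
        assert totals[Setting.PEDIATRIC].efficacy_rendered == "35%"
        dgs = {r.setting: r for r in rows if r.key == "dgs_vcfs"}
        assert dgs[Setting.PEDIATRIC].efficacy_rendered == "92%"
        assert dgs[Setting.PEDIATRIC].band is EfficacyBand.HIGHLY_EFFECTIVE
        assert dgs[Setting.PRENATAL].efficacy_rendered == "8%"
        assert dgs[Setting.PRENATAL].band is EfficacyBand.UNDER_DETECTION

    def test_exact_mode_uses_full_precision(self, reference_spectra):
        spectra = {
            s: (reference_spectra[s]["chromosomal"], reference_spectra[s]["pcnv"])
            for s in Setting
        }
        rows = build_efficacy_table(spectra, mode="exact")
        t21 = next(
            r for r in rows if r.key == "trisomy21" and r.setting is Setting.PRENATAL
        )
        assert t21.detected == pytest.approx(11.35)
        assert t21.expected == pytest.approx(10_000 / 830)
        assert t21.efficacy == pytest.approx(100 * 11.35 / (10_000 / 830))
        # no PWS/AS override in exact mode: all 31 tabulated deletions count
        pws = next(
            r for r in rows if r.key == "pws_as" and r.setting is Setting.PEDIATRIC
        )
        assert pws.detected_count == 31

    def test_zero_abnormal_cohort_all_under_detection(self, reference_spectra):
        from cytoyield.classify import classify_cohort
        from cytoyield.cohort import compute_denominators
        from cytoyield.rates import build_chromosomal_spectrum, build_pcnv_spectrum

        spectra = {}
        for setting in Setting:
            cases = [
                c.__class__(
                    case_id=c.case_id,
                    setting=c.setting,
                    year=c.year,
                    tests=c.tests,
                    fish_purpose=c.fish_purpose,
                    findings=(),
                )
                for c in reference_spectra[setting]["cases"][:50]
            ]
            cls = classify_cohort(cases)
            den = compute_denominators(cases, setting)
            spectra[setting] = (
                build_chromosomal_spectrum(cases, cls, den),
                build_pcnv_spectrum(cases, cls, den),
            )
        rows = build_efficacy_table(spectra)
        assert all(r.efficacy == 0 for r in rows)
        assert all(r.band is EfficacyBand.UNDER_DETECTION for r in rows)
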