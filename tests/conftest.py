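"""Shared fixtures: the deterministic reference cohort, classified once."""

from __future__ import annotations

import pytest

from cytoyield import reference_cohort
from cytoyield.classify import classify_cohort
from cytoyield.cohort import Setting, compute_denominators
from cytoyield.rates import build_chromosomal_spectrum, build_pcnv_spectrum


@pytest.fixture(scope="session")
def reference():
    """(cases, ledger) of the deterministic reference cohort."""
    return reference_cohort()


@pytest.fixture(scope="session")
def reference_spectra(reference):
    """Per-setting (chromosomal, pCNV) spectrum tables of the reference
    cohort, plus denominators, computed through the full pipeline."""
    cases, _ = reference
    out = {}
    for setting in Setting:
        subset = [c for c in cases if c.setting is setting]
        classifications = classify_cohort(subset)
        denominators = compute_denominators(subset, setting)
        out[setting] = {
            "cases": subset,
            "classifications": classifications,
            "denominators": denominators,
            "chromosomal": build_chromosomal_spectrum(subset, classifications, denominators),
            "pcnv": build_pcnv_spectrum(subset, classifications, denominators),
        }
    return out
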