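"""Loaders for the bundled reference spectrum tables and census."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import FishPurpose, Setting, TestModality

__all__ = ["load_reference_spectra", "reference_denominators"]


def _read(name: str) -> pd.DataFrame:
    path = resources.files("cytoyield.data").joinpath(name)
    with path.open("r", encoding="utf-8") as handle:
        return pd.read_csv(handle, sep="\t", comment="#", dtype=str, keep_default_na=False)


def reference_denominators() -> dict[Setting, dict[str, int]]:
    """Composite denominators implied by the reference test census."""
    census = _read("test_census.tsv")
    out: dict[Setting, dict[str, int]] = {}
    for setting in Setting:
        rows = census[census["setting"] == setting.value]
        chrom = pcnv = total = 0
        for _, row in rows.iterrows():
            tests = frozenset(TestModality(t) for t in row["tests"].split("|"))
            purpose = FishPurpose(row["fish_purpose"])
            count = int(row["count"])
            total += count
            fish_only = tests == frozenset({TestModality.FISH})
            if tests & {TestModality.KARYOTYPE, TestModality.ACGH} or (
                fish_only and purpose is FishPurpose.ANEUPLOIDY_PANEL
            ):
                chrom += count
            if TestModality.ACGH in tests or (
                fish_only and purpose is FishPurpose.TARGETED_MICRODELETION
            ):
                pcnv += count
        out[setting] = {"chromosomal": chrom, "pcnv": pcnv, "total": total}
    return out


def load_reference_spectra() -> tuple[pd.DataFrame, pd.DataFrame, dict[Setting, dict[str, int]]]:
    """(chromosomal reference, pCNV reference, census denominators)."""
    chrom = _read("chromosomal_spectrum_reference.tsv")
    pcnv = _read("pcnv_spectrum_reference.tsv")
    for frame in (chrom, pcnv):
        for col in ("prenatal_count", "pediatric_count"):
            frame[col] = frame[col].astype(int)
    return chrom, pcnv, reference_denominators()
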