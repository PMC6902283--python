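"""Loader for the bundled incidence/prevalence catalog."""

from __future__ import annotations

import csv
from importlib import resources
from typing import Union

import pandas as pd

__all__ = ["load_incidence_catalog"]


def _parse_value(cell: str) -> Union[float, tuple[float, float], None]:
    cell = cell.strip()
    if not cell:
        return None
    if "-" in cell:
        lo, hi = cell.split("-")
        return (float(lo), float(hi))
    return float(cell)


def load_incidence_catalog() -> pd.DataFrame:
    """The bundled epidemiological catalog.

    Columns: ``label``, ``context``, ``value`` (percent; a (lo, hi) tuple for
    reported ranges; None where only 1-in-N is given), ``one_in_n`` (int or
    None).
    """
    path = resources.files("cytoyield.data").joinpath("incidence_catalog.tsv")
    with path.open("r", encoding="utf-8") as handle:
        lines = [ln for ln in handle if not ln.startswith("#")]
    rows = []
    for row in csv.DictReader(lines, delimiter="\t"):
        one_in_n = (row.get("one_in_n") or "").strip()
        rows.append(
            {
                "label": row["label"],
                "context": row["context"],
                "value": _parse_value(row.get("value_percent") or ""),
                "one_in_n": int(one_in_n) if one_in_n else None,
            }
        )
    return pd.DataFrame(rows, columns=["label", "context", "value", "one_in_n"])
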