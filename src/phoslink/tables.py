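"""Bundled experimental reference tables.

The package ships the published measurements for the three compounds as
read-only CSV fixtures:

* table 3 -- MD-averaged inter-proton distances (A) for the NOE pairs
* table 4 -- relative NOE intensities (vs H1'-H2') at 283/303/323 K
* table 5 -- experimental and published-calculated 3J(C,P) couplings (Hz)
* table 6 -- experimental and published-calculated 3J(H,P) couplings (Hz)
* tables 1 and 2 -- 1H and 13C chemical shifts, carried as metadata only
  (no shift prediction is attempted)

``compound`` is 1, 2 or 3 for the 1->3, 1->4 and 1->6 linkage.  Values
are transcribed verbatim; the single inequality entry ("<2 Hz" for the
P-C3 coupling of compound 2) keeps its ``<`` marker in the ``qualifier``
column.
"""

from __future__ import annotations

import hashlib
from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = [
    "load_table",
    "lookup_experimental",
    "experimental_rows",
    "fixture_checksums",
    "TABLE_FILES",
]

TABLE_FILES = {
    1: "table1_h_shifts.csv",
    2: "table2_c_shifts.csv",
    3: "table3_distances.csv",
    4: "table4_noe_temperature.csv",
    5: "table5_jcp.csv",
    6: "table6_jhp.csv",
}

_VALUE_COLUMNS = {3: "distance_A", 4: "relative_noe", 5: "experimental_Hz", 6: "experimental_Hz"}


def _data_path(name: str):
    return resources.files("phoslink").joinpath("data", name)


@lru_cache(maxsize=None)
def load_table(table: int) -> pd.DataFrame:
    """Load one bundled table as a DataFrame (cached, treat as read-only)."""
    if table not in TABLE_FILES:
        raise KeyError(f"unknown table {table!r}; available: {sorted(TABLE_FILES)}")
    with resources.as_file(_data_path(TABLE_FILES[table])) as path:
        return pd.read_csv(path, dtype={"qualifier": "string"})


def experimental_rows(table: int, compound: int) -> pd.DataFrame:
    """All fixture rows of one table for one compound."""
    df = load_table(table)
    if "compound" not in df.columns:
        raise KeyError(f"table {table} has no per-compound rows")
    sub = df[df["compound"] == compound]
    if sub.empty:
        raise KeyError(
            f"no rows for compound {compound!r} in table {table}; "
            f"available compounds: {sorted(df['compound'].unique())}"
        )
    return sub.reset_index(drop=True)


def lookup_experimental(table: int, compound: int, pair: str, temperature_K: int | None = None) -> float:
    """The printed experimental value for one (table, compound, pair) key.

    Table 4 additionally needs a temperature.  Unknown keys raise
    ``KeyError`` listing the valid entries.
    """
    if table not in _VALUE_COLUMNS:
        raise KeyError(
            f"table {table!r} has no per-pair experimental values; valid tables: "
            f"{sorted(_VALUE_COLUMNS)}"
        )
    df = load_table(table)
    sel = df[(df["compound"] == compound) & (df["pair"] == pair)]
    if table == 4:
        if temperature_K is None:
            raise KeyError("table 4 lookups require temperature_K (283, 303 or 323)")
        sel = sel[sel["temperature_K"] == temperature_K]
    if len(sel) != 1:
        keys = sorted(
            (int(c), p) for c, p in zip(df["compound"], df["pair"])
        )
        raise KeyError(
            f"no entry for compound {compound!r}, pair {pair!r} in table {table}; "
            f"available (compound, pair) keys: {sorted(set(keys))}"
        )
    return float(sel.iloc[0][_VALUE_COLUMNS[table]])


def fixture_checksums() -> dict[str, str]:
    """SHA-256 checksums of the bundled fixture files."""
    out = {}
    for name in sorted(TABLE_FILES.values()):
        with resources.as_file(_data_path(name)) as path:
            out[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return out
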