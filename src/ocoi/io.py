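"""Bit-stable CSV I/O for tract tables.

Dialect: comma-separated, UTF-8, header row, ``fips`` always read and
written as a quoted string so leading-zero GEOIDs survive round trips.
Numeric output uses a fixed decimal precision (default 6) so identical
runs produce byte-identical files.
"""

from __future__ import annotations

import csv

import pandas as pd

__all__ = ["read_tract_table", "write_tract_table"]


def read_tract_table(path) -> pd.DataFrame:
    """Read a fips-keyed table, preserving the FIPS key as a string."""
    try:
        table = pd.read_csv(path, dtype={"fips": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if "fips" not in table.columns:
        raise ValueError(f"{path}: missing required 'fips' column")
    return table


def write_tract_table(table: pd.DataFrame, path, precision: int = 6) -> None:
    """Write a fips-keyed table with quoted strings and fixed precision."""
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(precision)
    out.to_csv(path, index=False, quoting=csv.QUOTE_NONNUMERIC)
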