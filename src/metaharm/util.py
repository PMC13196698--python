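"""Shared cell/token helpers and table I/O conventions.

Tables are pandas DataFrames of strings; missing data is ``NaN``.  On
disk, tables are TSV/CSV with a header, UTF-8, and NA encoded as an
empty field.  Files are read with pandas' default NA inference turned
off so that tokens like ``"NULL"`` or ``"missing"`` survive verbatim —
recoding those is the harmonization engine's job, not the reader's.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "is_na",
    "norm_token",
    "split_cell",
    "join_tokens",
    "read_table",
    "write_table",
]


def is_na(value) -> bool:
    """True for None/NaN/pd.NA scalar cells (never for strings)."""
    return value is None or (not isinstance(value, str) and pd.isna(value))


def norm_token(token: str) -> str:
    """Lookup normalization: trim, collapse internal whitespace, case-fold."""
    return " ".join(token.split()).casefold()


def split_cell(cell, delimiter: str = ";") -> list[str]:
    """Split a delimited cell into stripped, non-empty tokens; NA -> []."""
    if is_na(cell):
        return []
    return [tok.strip() for tok in str(cell).split(delimiter) if tok.strip()]


def join_tokens(tokens: list[str], delimiter: str = ";"):
    """Join tokens back into a cell; empty list -> NA (None)."""
    if not tokens:
        return None
    return delimiter.join(tokens)


def read_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV metadata table as strings, empty field = NA."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(
        path,
        sep=sep,
        dtype=str,
        keep_default_na=False,
        na_values=[""],
    )


def write_table(df: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    """Write a metadata table; NA becomes an empty field."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False, na_rep="")
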