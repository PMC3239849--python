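"""CSV schemas and round-trip-safe readers/writers for all pipeline tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .indicators import InputError, census_columns


def read_census_csv(path: str | Path) -> pd.DataFrame:
    """Read a DA-level aggregate census table.

    Validates the header against the documented schema (an error names every
    missing column), parses empty cells as missing values, and rejects
    duplicate DA identifiers.  Extra columns are preserved.
    """
    path = Path(path)
    header = pd.read_csv(path, nrows=0)
    missing = [c for c in census_columns() if c not in header.columns]
    if missing:
        raise InputError(f"{path.name}: missing required columns: {missing}")
    dtypes = {c: float for c in census_columns() if c not in ("da_id", "area_type")}
    try:
        table = pd.read_csv(path, dtype={"da_id": str, "area_type": str, **dtypes})
    except ValueError as exc:
        raise InputError(f"{path.name}: malformed numeric cell ({exc})") from exc
    if table["da_id"].duplicated().any():
        dupes = table.loc[table["da_id"].duplicated(), "da_id"].tolist()
        raise InputError(f"{path.name}: duplicate da_id values: {dupes[:5]}")
    return table


def write_census_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a census table; missing fields become empty cells."""
    table.to_csv(path, index=False)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_exclusion_log(log, path: str | Path) -> None:
    """Exclusion log as CSV (da_id, reason)."""
    log.records.to_csv(path, index=False)
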