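"""CSV time-series format for RCA measurement tables.

One minimal, documented dialect is used everywhere: comma-separated,
dot decimal, UTF-8, header row ``time_h,total_dna,ds_dna,ss_dna``, with
optional ``#``-prefixed comment lines carrying provenance (generating
parameters, seed, tool version).  Times are hours at the file interface
(matching how such time courses are reported) and converted to seconds
internally.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .synth import MeasurementTable

__all__ = ["REQUIRED_COLUMNS", "read_table", "write_table", "SchemaError"]

REQUIRED_COLUMNS = ("time_h", "total_dna", "ds_dna", "ss_dna")


class SchemaError(ValueError):
    """Raised when a CSV file does not match the time-series schema."""


def write_table(
    table: MeasurementTable,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write a measurement table as CSV with '#' provenance comments."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_frame().to_csv(fh, index=False)


def read_table(path: str | Path) -> MeasurementTable:
    """Read a measurement table, validating schema and ordering.

    Raises :class:`SchemaError` naming the offending column or row for
    missing columns, non-numeric values, or unsorted times.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in REQUIRED_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(values.isna() & df[col].notna())
        if bad.size or values.isna().any():
            row = int(bad[0]) if bad.size else int(np.flatnonzero(values.isna())[0])
            raise SchemaError(f"{path}: non-numeric or missing value in column "
                              f"'{col}' at data row {row}")
        df[col] = values
    t = df["time_h"].to_numpy()
    if np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise SchemaError(f"{path}: 'time_h' not strictly increasing at data row {row}")
    if np.any(t < 0):
        raise SchemaError(f"{path}: negative value in 'time_h'")
    return MeasurementTable(
        times_h=t,
        total_dna=df["total_dna"].to_numpy(),
        ds_dna=df["ds_dna"].to_numpy(),
        ss_dna=df["ss_dna"].to_numpy(),
    )
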