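"""Cohort table and results file handling.

Cohorts travel as delimited text (TSV by default, comma accepted) with a
header row and "NA" for missing values.  Reading validates the schema and
types; writing round-trips values at full precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["read_cohort", "write_cohort", "write_results", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("id", "instrument_score", "exposure")

_NUMERIC_COLUMNS = (
    "instrument_score",
    "exposure",
    "exposure_repeat",
    "age",
    "outcome_continuous",
)
_BINARY_COLUMNS = ("sex", "outcome_binary", "selected")


def read_cohort(
    path,
    required: Sequence[str] = REQUIRED_COLUMNS,
    sep: Optional[str] = None,
) -> pd.DataFrame:
    """Read a cohort table, validating schema and numeric types.

    ``sep=None`` sniffs the delimiter (tab or comma).  Raises with the
    column name when a required column is absent, and with the row number
    when a numeric column contains a non-numeric entry.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     na_values=["NA"], keep_default_na=True)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in (*_NUMERIC_COLUMNS, *_BINARY_COLUMNS):
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row + 1}"
            )
        df[col] = coerced
    for col in _BINARY_COLUMNS:
        if col in df.columns:
            vals = df[col].dropna()
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"{path}: column {col!r} must be coded 0/1")
    selected = df.get("selected")
    if selected is not None:
        mask = selected == 1
    else:
        mask = pd.Series(True, index=df.index)
    for col in ("instrument_score", "exposure"):
        if col in df.columns and df.loc[mask, col].isna().any():
            raise ValueError(f"{path}: missing {col!r} among selected rows")
    return df


def write_cohort(cohort: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a cohort as delimited text with full-precision floats."""
    cohort.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.17g")


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    return obj


def write_results(obj, path) -> None:
    """Serialise results to disk.

    DataFrames become TSV; anything else (dataclasses, dicts, arrays)
    becomes JSON.
    """
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")
        return
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
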