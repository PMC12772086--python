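"""CSV/TSV table reading and writing with light schema validation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError

_NA_TOKENS = ["", "NA"]

_DTYPE_CASTS = {
    "str": "object",
    "int": "Int64",
    "float": "float64",
}


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_table(path, schema: dict | None = None) -> pd.DataFrame:
    """Read a delimited table (dialect from extension, UTF-8, '' / 'NA' missing).

    ``schema`` maps column name -> one of ``str | int | float``; columns
    missing from the file, or values that fail to coerce, raise
    :class:`~bst.errors.SchemaError` naming the offending columns/rows.
    """
    frame = pd.read_csv(path, sep=_sep_for(path), na_values=_NA_TOKENS,
                        keep_default_na=False, encoding="utf-8")
    if schema is None:
        return frame
    missing = [c for c in schema if c not in frame.columns]
    if missing:
        raise SchemaError(f"table {path} does not match the expected schema",
                          missing=missing)
    for col, kind in schema.items():
        if kind == "str":
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            rows = list(np.flatnonzero(bad.to_numpy()))[:5]
            raise SchemaError(
                f"column '{col}' in {path} has non-{kind} values at rows {rows}"
            )
        if kind == "int":
            if (coerced.dropna() % 1 != 0).any():
                raise SchemaError(f"column '{col}' in {path} has non-integer values")
            frame[col] = coerced.astype("Int64")
        else:
            frame[col] = coerced.astype(float)
    return frame


def write_table(table: pd.DataFrame, path) -> None:
    """Write CSV/TSV with a header row; missing values as empty fields."""
    table.to_csv(path, sep=_sep_for(path), index=False, na_rep="",
                 float_format="%.10g", encoding="utf-8")
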