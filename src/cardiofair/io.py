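"""Reading and writing clinical cohorts in the UCI processed-CSV dialects.

Two dialects are supported:

``headerless-processed``
    The original repository layout: 14 comma-separated fields per row, no
    header, ``?`` for a missing value.
``headered``
    The same columns with a header row (common in redistributed copies).

Original target codes 1–4 (disease severity) are binarized to 1 on read.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import COLUMNS, Cohort, SchemaError

DIALECTS = ("headerless-processed", "headered")


class ParseError(ValueError):
    """A row of the input file does not match the 14-field layout."""


def read_uci_csv(path: str | Path, dialect: str = "headerless-processed") -> Cohort:
    """Parse a UCI-dialect CSV file into a validated :class:`Cohort`.

    ``?`` fields become explicit missing flags (NaN); targets greater than 1
    are binarized to 1.  A row with the wrong field count raises
    :class:`ParseError` naming the row; out-of-domain values raise
    :class:`~cardiofair.schema.SchemaError` naming the field.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if dialect == "headered":
        if not lines:
            raise ParseError("empty file: missing header row")
        header = [h.strip() for h in lines[0].split(",")]
        if header != list(COLUMNS):
            raise ParseError(f"unexpected header {header}")
        lines = lines[1:]
    rows = []
    for i, ln in enumerate(lines):
        fields = [f.strip() for f in ln.split(",")]
        if len(fields) != len(COLUMNS):
            raise ParseError(f"row {i}: expected {len(COLUMNS)} fields, got {len(fields)}")
        row = []
        for name, f in zip(COLUMNS, fields):
            if f == "?":
                row.append(np.nan)
            else:
                try:
                    row.append(float(f))
                except ValueError as exc:
                    raise ParseError(f"row {i}: field {name!r} is not numeric: {f!r}") from exc
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    if len(df):
        # severity codes 1-4 all mean "disease present"
        df["target"] = (df["target"] > 0).astype(float)
    return Cohort(df)


def write_uci_csv(cohort: Cohort, path: str | Path, dialect: str = "headerless-processed") -> None:
    """Write a cohort in the chosen dialect; missing values become ``?``."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    buf = _io.StringIO()
    if dialect == "headered":
        buf.write(",".join(COLUMNS) + "\n")
    for row in cohort.df.itertuples(index=False):
        fields = []
        for name in COLUMNS:
            v = getattr(row, name)
            if isinstance(v, float) and np.isnan(v):
                fields.append("?")
            elif float(v) == int(v) and name != "oldpeak":
                fields.append(str(int(v)))
            else:
                fields.append(repr(float(v)))
        buf.write(",".join(fields) + "\n")
    Path(path).write_text(buf.getvalue())
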