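"""Delimited-table input/output with schema checks and round-trip fidelity.

All pipeline artifacts are plain-text delimited tables with a header row and
the subject/dyad identifier in the first column. Floats are serialized with 17
significant digits so that write-then-read is the identity on values. Lines
starting with ``#`` are treated as comments (used for provenance headers).
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["read_table", "write_table", "SchemaError"]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if os.path.splitext(path)[1].lower() == ".csv" else "\t"


def read_table(
    path: str,
    required_columns: Sequence[str] | None = None,
    index_col: str | int | None = 0,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a delimited text table.

    The delimiter is auto-detected from the extension (``.csv`` is
    comma-separated, anything else tab-separated) unless ``delimiter``
    overrides it. ``required_columns`` are checked and a :class:`SchemaError`
    naming the missing columns is raised on mismatch.
    """
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, comment="#", index_col=index_col)
    if required_columns is not None:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def write_table(
    df: pd.DataFrame,
    path: str,
    delimiter: str | None = None,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write a table as delimited text (17 significant digits for floats).

    ``provenance`` key/value pairs are emitted as ``#``-prefixed header
    comment lines, which :func:`read_table` skips.
    """
    sep = _delimiter_for(path, delimiter)
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            for key, value in provenance.items():
                fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep=sep, float_format="%.17g")
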