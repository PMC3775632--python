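"""Readers and writers for signal tables and result files.

Signal tables are tab-delimited UTF-8, first column gene symbols.  The
2-D dialect carries sample IDs in the first header row and, optionally,
a second header row of group labels; that second row is recognized as a
group row precisely when *every* one of its data cells is non-numeric
(no magic keywords).  All result tables are written with a ``#``
reproducibility header recording the package version and the run
configuration, and re-parse losslessly with :func:`read_result_table`.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SignalTableError",
    "read_signal_table",
    "detect_mode",
    "write_result_table",
    "read_result_table",
]


class SignalTableError(ValueError):
    """Malformed signal table; message carries row/column coordinates."""


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except (TypeError, ValueError):
        return False


def read_signal_table(path: str | Path) -> tuple[pd.DataFrame, pd.Series | None]:
    """Read a gene-by-sample signal table.

    Returns ``(table, groups)`` where *table* is a float DataFrame
    indexed by upper-cased gene symbol and *groups* is a sample->label
    Series when a group-label row was present, else None.  Duplicate
    gene symbols are collapsed by mean (logged); a non-numeric data
    cell raises with its row/column coordinates.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        raise SignalTableError(f"{path}: empty table (need a header and data rows)")
    header = lines[0].split("\t")
    samples = header[1:]
    if not samples:
        raise SignalTableError(f"{path}: header names no sample columns")

    second = lines[1].split("\t")
    groups: pd.Series | None = None
    data_start = 1
    if len(second) == len(header) and all(not _is_number(c) for c in second[1:]):
        groups = pd.Series(
            [c.strip() for c in second[1:]], index=samples, dtype=object
        )
        data_start = 2

    genes: list[str] = []
    rows: list[list[float]] = []
    for offset, line in enumerate(lines[data_start:], start=data_start + 1):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise SignalTableError(
                f"{path}: line {offset} has {len(parts)} column(s); "
                f"expected {len(header)}"
            )
        vals = []
        for j, cell in enumerate(parts[1:], start=2):
            cell = cell.strip()
            if cell in ("", "NA", "NaN", "nan"):
                vals.append(np.nan)
            elif _is_number(cell):
                vals.append(float(cell))
            else:
                raise SignalTableError(
                    f"{path}: non-numeric value {cell!r} at line {offset}, column {j}"
                )
        genes.append(parts[0].strip().upper())
        rows.append(vals)
    if not rows:
        raise SignalTableError(f"{path}: no data rows")
    table = pd.DataFrame(rows, index=genes, columns=samples, dtype=float)
    if table.index.duplicated().any():
        n_dup = int(table.index.duplicated().sum())
        logger.warning("%s: %d duplicate gene row(s) collapsed by mean", path, n_dup)
        table = table.groupby(level=0, sort=False).mean()
    return table, groups


def detect_mode(table: pd.DataFrame, groups: pd.Series | None) -> str:
    """Resolve the analysis mode from the parsed table shape.

    One data column -> ``1d``; several -> ``2d``; 2-D with group labels
    exactly {positive, negative} (case-insensitive) -> ``classifier``.
    """
    if table.shape[1] == 1:
        return "1d"
    if groups is not None:
        labels = {str(g).strip().lower() for g in groups.dropna()}
        if labels == {"positive", "negative"}:
            return "classifier"
    return "2d"


def write_result_table(
    df: pd.DataFrame,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
    index: bool = False,
    index_label: str | None = None,
) -> None:
    """Write a result table as TSV with '#'-prefixed metadata header lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label,
                  lineterminator="\n", float_format="%.10g")


def read_result_table(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    """Re-parse a table written by :func:`write_result_table`."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
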