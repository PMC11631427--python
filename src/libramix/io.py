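"""Reading and writing count matrices, BCR tables, and run reports.

Count matrices travel either as delimited text (header row of antigen
names, first column of cell barcodes) or as matrix-market ``.mtx`` with
sidecar row/column name files (``<stem>.rows.txt`` / ``<stem>.cols.txt``,
one id per line).  BCR tables are tab-delimited with columns ``cell_id``,
``chain``, ``cdr3_aa``; the AIRR aliases ``junction_aa`` (for the CDR3)
and ``locus`` (IGH -> heavy, IGK/IGL -> light) are accepted and mapped.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import BcrTable, ScoreMatrix, UmiCountMatrix
from .errors import ParseError, ValidationError

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_bcr_table",
    "write_bcr_table",
    "write_score_matrix",
    "write_json",
]

_AIRR_ALIASES = {"junction_aa": "cdr3_aa", "locus": "chain"}
_LOCUS_MAP = {"IGH": "heavy", "IGK": "light", "IGL": "light"}


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.rows.txt"), Path(f"{stem}.cols.txt")


def read_count_matrix(path, fmt: str | None = None, delimiter: str = ",") -> UmiCountMatrix:
    """Read a cells x antigens UMI count matrix from csv or mtx.

    ``fmt`` is inferred from the suffix when omitted.  Non-integer or
    negative entries are rejected; duplicate ids raise a validation error.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "csv"
    if fmt == "csv":
        try:
            df = pd.read_csv(path, sep=delimiter, index_col=0)
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise ParseError(f"{path}: {exc}") from exc
        for col in df.columns:
            if not pd.api.types.is_numeric_dtype(df[col]):
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
                raise ParseError(
                    f"{path}: non-numeric entry {bad.iloc[0]!r} in column {col!r} "
                    f"(cell {bad.index[0]!r})")
        counts = df.to_numpy()
        return UmiCountMatrix(list(df.index.astype(str)),
                              list(df.columns.astype(str)), counts)
    if fmt == "mtx":
        rows_path, cols_path = _sidecar_paths(path)
        for p in (rows_path, cols_path):
            if not p.exists():
                raise ParseError(f"missing sidecar name file {p}")
        try:
            mat = spio.mmread(path)
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
        cells = rows_path.read_text().splitlines()
        antigens = cols_path.read_text().splitlines()
        counts = np.asarray(sparse.coo_matrix(mat).todense())
        return UmiCountMatrix(cells, antigens, counts)
    raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'mtx'")


def write_count_matrix(matrix: UmiCountMatrix, path, fmt: str | None = None,
                       delimiter: str = ",") -> None:
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "csv"
    if fmt == "csv":
        matrix.to_frame().to_csv(path, sep=delimiter)
    elif fmt == "mtx":
        rows_path, cols_path = _sidecar_paths(path)
        spio.mmwrite(path, sparse.coo_matrix(matrix.counts))
        rows_path.write_text("\n".join(matrix.cell_ids) + "\n")
        cols_path.write_text("\n".join(matrix.antigen_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_bcr_table(path) -> BcrTable:
    """Read a tab-delimited BCR chain table, mapping AIRR column aliases."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    df = df.rename(columns={k: v for k, v in _AIRR_ALIASES.items()
                            if v not in df.columns})
    if "chain" in df.columns:
        df["chain"] = df["chain"].map(lambda c: _LOCUS_MAP.get(c, c))
    missing = {"cell_id", "chain", "cdr3_aa"} - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing columns {sorted(missing)} "
            "(accepted aliases: junction_aa, locus)")
    return BcrTable(df)


def write_bcr_table(bcr: BcrTable, path) -> None:
    bcr.records.to_csv(path, sep="\t", index=False)


def write_score_matrix(scores: ScoreMatrix, path, delimiter: str = ",") -> None:
    scores.to_frame().to_csv(path, sep=delimiter)


def write_json(obj, path) -> None:
    """Deterministic JSON output (sorted keys, fixed separators)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
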