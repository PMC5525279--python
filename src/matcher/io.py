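"""Readers and writers for cell-by-feature matrices and result tables.

Dense matrices are TSV/CSV with a ``cell_id`` first column and a header row
of feature IDs. Sparse matrices are MatrixMarket coordinate files with
``rows.txt`` (cell IDs) and ``cols.txt`` (feature IDs) sidecars in the same
directory. All text is UTF-8 with '.' as the decimal separator.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import CellFeatureMatrix, MatcherError, _find_duplicates

logger = logging.getLogger("matcher")

_SEPS = {"tsv": "\t", "csv": ","}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "csv", "mtx", "txt"):
        return "tsv" if suffix == "txt" else suffix
    raise MatcherError(f"cannot infer format from {path.name!r}; pass format explicitly")


def read_matrix(path, format: Optional[str] = None, modality_name: Optional[str] = None,
                transpose: bool = False, impute_missing: bool = False) -> CellFeatureMatrix:
    """Read a cell-by-feature matrix from TSV/CSV or MTX-triplet files.

    Missing values are rejected unless ``impute_missing`` is set, in which
    case per-feature mean imputation is applied and the count logged.
    Set ``transpose`` for files stored features-in-rows.
    """
    path = Path(path)
    if not path.exists():
        raise MatcherError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt in _SEPS:
        df = _read_dense(path, _SEPS[fmt])
    elif fmt == "mtx":
        df = _read_mtx(path)
    else:
        raise MatcherError(f"unknown format {fmt!r}; expected tsv, csv or mtx")
    if transpose:
        df = df.T
        df.index.name = "cell_id"
    df = _apply_missing_policy(df, impute_missing, path)
    name = modality_name or path.stem
    return CellFeatureMatrix.from_dataframe(df, modality_name=name)


def _read_dense(path: Path, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str,
                         keep_default_na=False, na_values=["", "NA", "NaN", "nan"])
    except pd.errors.ParserError as exc:
        raise MatcherError(f"{path}: ragged or malformed rows ({exc})") from exc
    df.index = df.index.astype(str)
    dup = _find_duplicates(list(df.index))
    if dup:
        raise MatcherError(f"{path}: duplicate cell IDs: {dup}")
    dupf = _find_duplicates(list(df.columns))
    if dupf:
        raise MatcherError(f"{path}: duplicate feature IDs: {dupf}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise MatcherError(
                f"{path}: non-numeric value {df[col].iloc[i]!r} at row "
                f"{df.index[i]!r} (data row {i + 1}), column {col!r} (column {j + 1})"
            )
        out[col] = coerced
    out.index.name = "cell_id"
    return out


def _read_mtx(path: Path) -> pd.DataFrame:
    rows_file = path.parent / "rows.txt"
    cols_file = path.parent / "cols.txt"
    for side in (rows_file, cols_file):
        if not side.exists():
            raise MatcherError(f"missing sidecar label file: {side}")
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    cell_ids = rows_file.read_text().split()
    feature_ids = cols_file.read_text().split()
    if mat.shape != (len(cell_ids), len(feature_ids)):
        raise MatcherError(
            f"{path}: matrix shape {mat.shape} does not match "
            f"{len(cell_ids)} row labels x {len(feature_ids)} column labels"
        )
    for ids, what in ((cell_ids, "cell"), (feature_ids, "feature")):
        dup = _find_duplicates(ids)
        if dup:
            raise MatcherError(f"{path}: duplicate {what} IDs: {dup}")
    df = pd.DataFrame(mat, index=cell_ids, columns=feature_ids)
    df.index.name = "cell_id"
    return df


def _apply_missing_policy(df: pd.DataFrame, impute: bool, path: Path) -> pd.DataFrame:
    n_missing = int(df.isna().to_numpy().sum())
    if n_missing == 0:
        return df
    if not impute:
        cell, feat = np.argwhere(df.isna().to_numpy())[0]
        raise MatcherError(
            f"{path}: {n_missing} missing value(s), first at cell "
            f"{df.index[cell]!r}, feature {df.columns[feat]!r}; rerun with "
            "imputation enabled to mean-impute per feature"
        )
    logger.info("imputing %d missing value(s) in %s with per-feature means", n_missing, path)
    return df.fillna(df.mean(axis=0))


def write_matrix(matrix: CellFeatureMatrix, path, sep: str = "\t") -> None:
    atomic_write_text(path, matrix.to_dataframe().to_csv(sep=sep, float_format="%.17g"))


_MASTER_COLUMNS = ["cell_id", "modality", "pseudotime", "master_time"]


def write_master_time_table(records: Iterable[dict], path) -> None:
    """Write per-cell (cell_id, modality, pseudotime, master_time) records as TSV.

    master_time must lie in [0, 1]; values outside that range indicate a
    broken warping upstream and are refused.
    """
    rows = list(records)
    df = pd.DataFrame(rows)
    missing = [c for c in _MASTER_COLUMNS if c not in df.columns]
    if missing:
        raise MatcherError(f"records missing fields: {missing}")
    df = df[_MASTER_COLUMNS]
    mt = df["master_time"].to_numpy(dtype=float)
    bad = (mt < 0) | (mt > 1) | ~np.isfinite(mt)
    if bad.any():
        i = int(np.argmax(bad))
        raise MatcherError(
            f"master_time {mt[i]!r} for cell {df['cell_id'].iloc[i]!r} outside [0, 1]"
        )
    atomic_write_text(path, df.to_csv(sep="\t", index=False, float_format="%.17g"))


def read_master_time_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "modality": str})
    missing = [c for c in _MASTER_COLUMNS if c not in df.columns]
    if missing:
        raise MatcherError(f"{path}: missing columns {missing}")
    return df


def atomic_write_text(path, text: str) -> None:
    """Write-then-rename so a failure never leaves a half-written output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)
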