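"""Readers and writers for the pipeline's on-disk formats.

Single-cell counts travel as a MatrixMarket coordinate triplet (1-based
indices) with features.tsv / barcodes.tsv sidecars; bulk matrices as TSV
with gene ids in the first column; metadata as CSV; gene sets as GMT;
reports as JSON. All expression files are genes-as-rows - orientation is
never auto-detected. Gene identifiers are matched case-sensitively after
whitespace stripping, and duplicate (row, col) triplet entries are summed
with a warning.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import (
    BulkExpression,
    CellCounts,
    SAMPLE_META_COLUMNS,
    validate_sample_meta,
)


def _read_lines(path: Path) -> list[str]:
    return Path(path).read_text().splitlines()


def read_single_cell(matrix_path, features_path, barcodes_path) -> CellCounts:
    """Read a MatrixMarket triplet with feature/barcode sidecars.

    The coordinate entries must be 1-based; out-of-bounds or non-positive
    indices raise a parse error naming the offending line. Duplicate
    (row, col) entries are summed with a warning.
    """
    genes = pd.Index(
        [ln.strip().split("\t")[0] for ln in _read_lines(features_path) if ln.strip()],
        name="gene",
    )
    cells = pd.Index(
        [ln.strip().split("\t")[0] for ln in _read_lines(barcodes_path) if ln.strip()],
        name="cell_id",
    )
    lines = _read_lines(matrix_path)
    if not lines or not lines[0].startswith("%%MatrixMarket"):
        raise ValueError(f"{matrix_path}: missing MatrixMarket header")
    body_start = 1
    while body_start < len(lines) and lines[body_start].lstrip().startswith("%"):
        body_start += 1
    try:
        n_rows, n_cols, n_entries = map(int, lines[body_start].split())
    except Exception as exc:
        raise ValueError(f"{matrix_path}:{body_start + 1}: bad dimensions line") from exc
    if n_rows != len(genes):
        raise ValueError(
            f"{matrix_path}: header declares {n_rows} rows but features file "
            f"has {len(genes)} entries"
        )
    if n_cols != len(cells):
        raise ValueError(
            f"{matrix_path}: header declares {n_cols} columns but barcodes "
            f"file has {len(cells)} entries"
        )
    rows = np.empty(n_entries, dtype=np.int64)
    cols = np.empty(n_entries, dtype=np.int64)
    vals = np.empty(n_entries, dtype=np.int64)
    k = 0
    for off, ln in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not ln.strip():
            continue
        parts = ln.split()
        if len(parts) != 3:
            raise ValueError(f"{matrix_path}:{off}: expected 'row col value'")
        r, c, v = int(parts[0]), int(parts[1]), int(float(parts[2]))
        if r < 1 or r > n_rows or c < 1 or c > n_cols:
            raise ValueError(
                f"{matrix_path}:{off}: index ({r}, {c}) outside 1-based bounds "
                f"({n_rows}, {n_cols})"
            )
        if k >= n_entries:
            raise ValueError(f"{matrix_path}:{off}: more entries than declared")
        rows[k], cols[k], vals[k] = r - 1, c - 1, v
        k += 1
    if k != n_entries:
        raise ValueError(f"{matrix_path}: {k} entries found, {n_entries} declared")
    coo = sparse.coo_matrix((vals, (rows, cols)), shape=(n_rows, n_cols))
    if coo.nnz != len(np.unique(rows * n_cols + cols)):
        warnings.warn(f"{matrix_path}: duplicate entries summed")
    return CellCounts(coo.tocsr(), genes, cells)


def write_single_cell(counts: CellCounts, out_dir) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mtx = out_dir / "matrix.mtx"
    coo = counts.matrix.tocoo()
    with mtx.open("w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{counts.shape[0]} {counts.shape[1]} {coo.nnz}\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r + 1} {c + 1} {int(v)}\n")
    feats = out_dir / "features.tsv"
    feats.write_text("".join(f"{g}\n" for g in counts.genes))
    bars = out_dir / "barcodes.tsv"
    bars.write_text("".join(f"{c}\n" for c in counts.cells))
    return {"matrix": mtx, "features": feats, "barcodes": bars}


def read_bulk(path, scale: str = "linear") -> BulkExpression:
    """Read a genes x samples TSV (gene ids in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    if df.index.duplicated().any():
        warnings.warn(f"{path}: duplicated gene ids collapsed by sum")
        df = df.groupby(level=0).sum()
    for col in df.columns:
        if df[col].dtype == object:
            conv = pd.to_numeric(df[col], errors="coerce")
            bad = conv.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad][0]
                raise ValueError(
                    f"{path}: non-numeric expression value at gene {gene!r}, "
                    f"sample {col!r}"
                )
            df[col] = conv
    return BulkExpression(df.astype(float), scale=scale)


def write_bulk(bulk: BulkExpression, path) -> Path:
    path = Path(path)
    bulk.matrix.rename_axis(index="gene").to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, index_col=0)
    missing = [c for c in SAMPLE_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: sample metadata missing columns {missing}")
    validate_sample_meta(meta)
    return meta


def read_cell_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, index_col=0)
    required = ["donor", "batch", "origin", "sex", "technical_replicate"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: cell metadata missing columns {missing}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> Path:
    path = Path(path)
    meta.to_csv(path)
    return path


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: set id, description, then genes."""
    sets: dict[str, set[str]] = {}
    for ln in _read_lines(path):
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT lines need id, description, >=1 gene")
        sets[parts[0]] = {g.strip() for g in parts[2:] if g.strip()}
    return sets


def write_json(obj, path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (pd.Series,)):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default, allow_nan=True) + "\n")
    return path
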