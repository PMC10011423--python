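"""In-memory data containers shared by the pipeline stages.

Expression matrices are stored genes-as-rows throughout the package: single
cell counts as a sparse genes x cells matrix, bulk expression as a dense
genes x samples frame. Per-cell and per-sample annotations travel as pandas
DataFrames indexed by cell or sample id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

CELL_META_COLUMNS = (
    "donor",
    "batch",
    "origin",
    "sex",
    "technical_replicate",
    "cell_type",
)

SAMPLE_META_COLUMNS = ("case", "gestational_age", "fetal_sex", "study")


@dataclass
class CellCounts:
    """Raw single-cell UMI counts, genes x cells, with string identifiers."""

    matrix: sparse.csr_matrix
    genes: pd.Index
    cells: pd.Index

    def __post_init__(self) -> None:
        self.matrix = sparse.csr_matrix(self.matrix)
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if self.matrix.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not self.genes.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.cells.is_unique:
            raise ValueError("cell ids must be unique")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def subset_cells(self, cell_ids) -> "CellCounts":
        idx = self.cells.get_indexer(pd.Index(cell_ids))
        if (idx < 0).any():
            missing = pd.Index(cell_ids)[idx < 0][:5].tolist()
            raise KeyError(f"unknown cell ids, e.g. {missing}")
        return CellCounts(self.matrix[:, idx], self.genes, pd.Index(cell_ids))

    def to_anndata(self):
        """Convert to an AnnData (cells x genes) for interoperability."""
        import anndata as ad

        return ad.AnnData(
            X=self.matrix.T.tocsr(),
            obs=pd.DataFrame(index=self.cells.astype(str)),
            var=pd.DataFrame(index=self.genes.astype(str)),
        )


@dataclass
class NormalizedCells:
    """Library-size log-normalized expression: ln(1 + 1e4 * x / cell_total)."""

    matrix: sparse.csr_matrix
    genes: pd.Index
    cells: pd.Index
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        self.matrix = sparse.csr_matrix(self.matrix)
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass
class BulkExpression:
    """Bulk expression matrix (genes x samples) with an explicit scale flag.

    ``scale`` is "linear" or "log2"; log2 values are interpreted as
    log2(1 + linear) and de-logged before any mixing-model computation.
    """

    matrix: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale flag {self.scale!r}")
        if not np.isfinite(self.matrix.to_numpy(dtype=float)).all():
            raise ValueError("bulk expression must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def samples(self) -> pd.Index:
        return self.matrix.columns

    def to_linear(self) -> pd.DataFrame:
        if self.scale == "linear":
            return self.matrix
        return np.exp2(self.matrix) - 1.0


def validate_cell_meta(meta: pd.DataFrame, cells: pd.Index | None = None) -> None:
    missing = [c for c in CELL_META_COLUMNS if c not in meta.columns and c != "cell_type"]
    if missing:
        raise ValueError(f"cell metadata missing required columns: {missing}")
    if cells is not None:
        if not meta.index.equals(pd.Index(cells)):
            if set(meta.index) != set(cells):
                raise ValueError("cell metadata rows do not match count matrix cells")


def validate_sample_meta(meta: pd.DataFrame) -> None:
    missing = [c for c in SAMPLE_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing required columns: {missing}")
    ga = meta["gestational_age"].astype(float)
    if ((ga <= 20) | (ga >= 45)).any():
        raise ValueError("gestational_age must lie in (20, 45) weeks")
    if meta[list(SAMPLE_META_COLUMNS)].isna().any().any():
        raise ValueError("sample metadata contains missing covariate values")
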