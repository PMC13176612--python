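"""Count-matrix containers and readers/writers.

Supports the two interchange formats used throughout the package:

* ``mtx10x`` — MatrixMarket coordinate file plus ``barcodes.tsv`` and
  ``features.tsv`` (or ``genes.tsv``) sidecars, stored genes x cells on disk
  per the 10x CellRanger / STARsolo convention and transposed to
  cells x genes on read.
* ``csv`` — dense table with cells as rows, a header row of gene ids and the
  first column holding cell ids.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import (
    DuplicateIdentifierError,
    MissingSidecarError,
    NonIntegerEntryError,
)

__all__ = ["CountMatrix", "read_counts", "write_counts"]


@dataclass
class CountMatrix:
    """Raw nonnegative integer counts, cells x genes.

    Parameters
    ----------
    values
        Sparse (CSR) or dense nonnegative integer matrix, one row per cell.
    cell_ids, gene_ids
        Unique identifiers aligned with rows and columns respectively.
    """

    values: sp.csr_matrix
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        self.values = self.values.tocsr()
        n, g = self.values.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(g)]
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError(
                f"identifier lengths ({len(self.cell_ids)}, {len(self.gene_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        if len(set(self.cell_ids)) != n:
            raise DuplicateIdentifierError("cell identifiers are not unique")
        if len(set(self.gene_ids)) != g:
            raise DuplicateIdentifierError("gene identifiers are not unique")
        data = self.values.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise NonIntegerEntryError(
                "count matrix entries must be nonnegative integers"
            )
        self.values.data = np.asarray(np.round(data), dtype=np.int64)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def toarray(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def zero_fraction(self) -> float:
        """Fraction of entries that are (implicit or explicit) zeros."""
        nnz = int((self.values != 0).sum())
        total = self.n_cells * self.n_genes
        return 1.0 - nnz / total

    def subset(self, cells=None, genes=None) -> "CountMatrix":
        """Return a new CountMatrix restricted to the given row/column indices."""
        vals = self.values
        cids, gids = self.cell_ids, self.gene_ids
        if cells is not None:
            cells = np.asarray(cells)
            vals = vals[cells]
            cids = [self.cell_ids[i] for i in cells]
        if genes is not None:
            genes = np.asarray(genes)
            vals = vals[:, genes]
            gids = [self.gene_ids[j] for j in genes]
        return CountMatrix(vals.tocsr(), list(cids), list(gids))


def _find_sidecar(directory: str, names: tuple[str, ...]) -> str:
    for name in names:
        cand = os.path.join(directory, name)
        if os.path.exists(cand):
            return cand
    raise MissingSidecarError(
        f"none of {names} found next to the matrix in {directory!r}"
    )


def _read_ids(path: str) -> list[str]:
    # barcodes.tsv is single-column; features.tsv may have extra columns
    # (id, symbol, feature type) -- the first column is the identifier.
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def read_counts(path: str, format: str = "mtx10x") -> CountMatrix:
    """Read a count matrix from disk.

    For ``mtx10x``, *path* is the ``.mtx`` file (or a directory containing
    ``matrix.mtx``); barcodes and features sidecars must sit alongside it.
    The on-disk orientation is genes x cells and is transposed on read;
    entries absent from the coordinate file are zeros.
    """
    if format == "mtx10x":
        if os.path.isdir(path):
            path = os.path.join(path, "matrix.mtx")
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        directory = os.path.dirname(os.path.abspath(path))
        barcodes = _find_sidecar(directory, ("barcodes.tsv",))
        features = _find_sidecar(directory, ("features.tsv", "genes.tsv"))
        mat = scipy.io.mmread(path)  # genes x cells on disk
        if not np.issubdtype(mat.dtype, np.integer):
            dense_ok = np.all(mat.data == np.round(mat.data)) if sp.issparse(mat) else np.all(mat == np.round(mat))
            if not dense_ok:
                raise NonIntegerEntryError(f"{path} contains non-integer entries")
        gene_ids = _read_ids(features)
        cell_ids = _read_ids(barcodes)
        return CountMatrix(sp.csr_matrix(mat.T), cell_ids, gene_ids)
    if format == "csv":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy()
        if not np.all(values == np.round(values)):
            raise NonIntegerEntryError(f"{path} contains non-integer entries")
        return CountMatrix(
            sp.csr_matrix(values.astype(np.int64)),
            [str(c) for c in df.index],
            [str(g) for g in df.columns],
        )
    raise ValueError(f"unknown format {format!r}; expected 'mtx10x' or 'csv'")


def write_counts(m: CountMatrix, path: str, format: str = "mtx10x") -> None:
    """Write a count matrix; inverse of :func:`read_counts` for both formats."""
    if format == "mtx10x":
        directory = os.path.dirname(os.path.abspath(path))
        os.makedirs(directory, exist_ok=True)
        scipy.io.mmwrite(path, m.values.T.tocoo(), field="integer")
        # mmwrite appends .mtx if missing; mirror that for the sidecars
        pd.Series(m.cell_ids).to_csv(
            os.path.join(directory, "barcodes.tsv"), sep="\t", index=False, header=False
        )
        pd.Series(m.gene_ids).to_csv(
            os.path.join(directory, "features.tsv"), sep="\t", index=False, header=False
        )
        return
    if format == "csv":
        df = pd.DataFrame(m.toarray(), index=m.cell_ids, columns=m.gene_ids)
        df.to_csv(path)
        return
    raise ValueError(f"unknown format {format!r}; expected 'mtx10x' or 'csv'")
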