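"""Reading count matrices, barcode-level cell selection, and gene-axis harmonization.

Matrices are stored genes x cells with non-negative integer UMI counts.
All indices are 0-based internally; Matrix Market files are 1-based per the
standard.  Gene identity is the symbol string, case-sensitive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "CountMatrix",
    "make_cell_table",
    "read_counts",
    "filter_cells_by_tag",
    "filter_cells_by_gene_positive",
    "harmonize_genes",
]

#: Canonical columns of a per-cell metadata table.
CELL_TABLE_COLUMNS = ["barcode", "dataset_id", "tissue_tag", "cluster_id", "subpop"]


@dataclass
class CountMatrix:
    """A genes x cells UMI count matrix with its axis metadata.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_cells)`` array of non-negative integers.
    gene_symbols
        Unique gene symbols, one per row.
    barcodes
        Unique cell barcodes, one per column.
    dataset_id
        Identifier of the source dataset.
    zero_filled
        Boolean mask over genes marking rows that were zero-filled during
        union-mode harmonization (absent from the original dataset).
    """

    values: np.ndarray
    gene_symbols: np.ndarray
    barcodes: np.ndarray
    dataset_id: str
    zero_filled: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-dimensional (genes x cells)")
        if self.values.shape != (len(self.gene_symbols), len(self.barcodes)):
            raise ValueError(
                f"dimension mismatch: matrix {self.values.shape} vs "
                f"{len(self.gene_symbols)} genes / {len(self.barcodes)} barcodes"
            )
        if np.any(self.values < 0):
            raise ValueError("count matrix contains negative entries")
        for name, arr in (("gene symbols", self.gene_symbols), ("barcodes", self.barcodes)):
            uniq, counts = np.unique(arr.astype(str), return_counts=True)
            if len(uniq) != len(arr):
                dupes = uniq[counts > 1][:10].tolist()
                raise ValueError(f"duplicate {name}: {dupes}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Total UMI count per cell."""
        return self.values.sum(axis=0)

    def gene_index(self, symbol: str) -> int:
        idx = np.flatnonzero(self.gene_symbols == symbol)
        if len(idx) == 0:
            raise KeyError(f"gene {symbol!r} not present in dataset {self.dataset_id!r}")
        return int(idx[0])

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return replace(
            self,
            values=self.values[:, mask],
            barcodes=self.barcodes[mask],
        )


def make_cell_table(
    barcodes: Sequence[str],
    dataset_id: str,
    tissue_tags: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build a fresh per-cell metadata table with canonical columns."""
    n = len(barcodes)
    return pd.DataFrame(
        {
            "barcode": list(barcodes),
            "dataset_id": dataset_id,
            "tissue_tag": list(tissue_tags) if tissue_tags is not None else [None] * n,
            "cluster_id": pd.array([None] * n, dtype="Int64"),
            "subpop": pd.array([None] * n, dtype="string"),
        }
    )


def _read_mtx_triplet(path: str) -> CountMatrix:
    matrix_path = os.path.join(path, "matrix.mtx")
    barcodes_path = os.path.join(path, "barcodes.tsv")
    features_path = os.path.join(path, "features.tsv")
    for p in (matrix_path, barcodes_path, features_path):
        if not os.path.exists(p):
            raise FileNotFoundError(f"MTX triplet incomplete: missing {p}")
    mat = spio.mmread(matrix_path)
    values = np.asarray(sparse.coo_matrix(mat).todense()).astype(np.int64)
    genes = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str).to_numpy()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).to_numpy()
    if values.shape[0] != len(genes):
        raise ValueError(
            f"features.tsv has {len(genes)} genes but matrix has {values.shape[0]} rows"
        )
    if values.shape[1] != len(barcodes):
        raise ValueError(
            f"barcodes.tsv has {len(barcodes)} barcodes but matrix has {values.shape[1]} columns"
        )
    return CountMatrix(values, genes, barcodes, dataset_id=os.path.basename(os.path.normpath(path)))


def _read_csv_matrix(path: str) -> CountMatrix:
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        rounded = np.rint(values)
        if not np.allclose(values, rounded):
            raise ValueError("CSV count matrix contains non-integer values")
        values = rounded.astype(np.int64)
    name = os.path.splitext(os.path.basename(path))[0]
    return CountMatrix(
        values.astype(np.int64),
        df.index.astype(str).to_numpy(),
        df.columns.astype(str).to_numpy(),
        dataset_id=name,
    )


def read_counts(
    path: str,
    format: Literal["mtx", "csv"] = "mtx",
    dataset_id: str | None = None,
) -> CountMatrix:
    """Read a UMI count matrix from disk.

    ``mtx`` expects a directory holding ``matrix.mtx`` (genes x cells),
    ``barcodes.tsv`` and ``features.tsv``; ``csv`` expects a dense matrix with
    gene symbols as the index and barcodes as the header.  Integer counts are
    preserved exactly.
    """
    if format == "mtx":
        cm = _read_mtx_triplet(path)
    elif format == "csv":
        cm = _read_csv_matrix(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'mtx' or 'csv'")
    if dataset_id is not None:
        cm = replace(cm, dataset_id=dataset_id)
    return cm


def _aligned_table(cm: CountMatrix, table: pd.DataFrame) -> pd.DataFrame:
    sub = table[table["dataset_id"] == cm.dataset_id]
    sub = sub.set_index("barcode").loc[list(cm.barcodes)].reset_index()
    return sub


def filter_cells_by_tag(
    cm: CountMatrix,
    table: pd.DataFrame,
    predicate: Callable[[pd.Series], bool] | str,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Retain only cells whose metadata row satisfies ``predicate``.

    ``predicate`` is either a callable on a metadata row or a tissue-tag
    string to keep (the common CLI case, ``--keep-tag liver``).  The gene
    axis and the retained counts are untouched.
    """
    aligned = _aligned_table(cm, table)
    if isinstance(predicate, str):
        tag = predicate
        keep = (aligned["tissue_tag"] == tag).to_numpy()
    else:
        keep = aligned.apply(predicate, axis=1).to_numpy(dtype=bool)
    if not keep.any():
        raise ValueError(
            f"tag filter removed every cell of dataset {cm.dataset_id!r}; "
            "an empty dataset is meaningless downstream"
        )
    return cm.subset_cells(keep), aligned[keep].reset_index(drop=True)


def filter_cells_by_gene_positive(
    cm: CountMatrix,
    table: pd.DataFrame,
    gene: str,
    min_count: int = 1,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Retain cells with at least ``min_count`` UMIs of ``gene`` (e.g. CD45+/PTPRC selection)."""
    gi = cm.gene_index(gene)
    keep = cm.values[gi, :] >= min_count
    if not keep.any():
        raise ValueError(
            f"no cell has >= {min_count} counts of {gene!r} in dataset {cm.dataset_id!r}"
        )
    aligned = _aligned_table(cm, table)
    return cm.subset_cells(keep), aligned[keep].reset_index(drop=True)


def harmonize_genes(
    matrices: Iterable[CountMatrix],
    mode: Literal["intersection", "union"] = "intersection",
) -> list[CountMatrix]:
    """Place all matrices on an identical, sorted gene axis.

    ``intersection`` (default) keeps only genes present in every dataset —
    the appropriate choice before cross-dataset DE, since union zero-fill
    manufactures artificial differential expression.  ``union`` keeps all
    genes, zero-filling absent ones and flagging them in ``zero_filled``.
    """
    matrices = list(matrices)
    if len(matrices) < 2:
        raise ValueError("harmonization requires at least 2 datasets")
    sets = [set(m.gene_symbols.astype(str)) for m in matrices]
    if mode == "intersection":
        shared = set.intersection(*sets)
        if not shared:
            raise ValueError("gene intersection across datasets is empty")
        genes = np.array(sorted(shared), dtype=object)
    elif mode == "union":
        genes = np.array(sorted(set.union(*sets)), dtype=object)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = []
    for cm in matrices:
        lookup = {g: i for i, g in enumerate(cm.gene_symbols)}
        values = np.zeros((len(genes), cm.n_cells), dtype=cm.values.dtype)
        filled = np.ones(len(genes), dtype=bool)
        for j, g in enumerate(genes):
            i = lookup.get(g)
            if i is not None:
                values[j, :] = cm.values[i, :]
                filled[j] = False
        out.append(
            CountMatrix(
                values,
                genes.copy(),
                cm.barcodes.copy(),
                dataset_id=cm.dataset_id,
                zero_filled=filled if mode == "union" else None,
            )
        )
    return out
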