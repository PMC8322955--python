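"""Meta-atlas assembly, per-subpopulation DE against a reference compartment,
and gene-to-function chord-plot edge export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corepipe import NormalizedMatrix
from .diffexp import de_between_datasets

__all__ = [
    "FunctionMap",
    "build_meta_atlas",
    "de_vs_reference",
    "extract_signatures",
    "link_functions",
]


@dataclass
class FunctionMap:
    """Mapping gene symbol -> set of cell-function labels, with provenance.

    Labels must come from the declared controlled vocabulary.
    """

    mapping: dict[str, set[str]]
    vocabulary: set[str]
    provenance: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for g, labels in self.mapping.items():
            bad = labels - self.vocabulary
            if bad:
                raise ValueError(f"labels for {g!r} outside vocabulary: {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path: str) -> "FunctionMap":
        """Read a two-column (gene, function) TSV, one pair per line."""
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "function"])
        mapping: dict[str, set[str]] = {}
        for _, row in df.iterrows():
            mapping.setdefault(str(row["gene"]), set()).add(str(row["function"]))
        vocab = {str(f) for f in df["function"]}
        return cls(mapping=mapping, vocabulary=vocab, provenance={"source": path})


def build_meta_atlas(
    matrices: Sequence[NormalizedMatrix],
    cell_tables: Sequence[pd.DataFrame],
) -> tuple[NormalizedMatrix, pd.DataFrame]:
    """Concatenate annotated datasets into one atlas, keeping provenance.

    Barcodes remain traceable to (dataset, barcode); subpopulation labels
    are carried through.  Requires all cells to be annotated.
    """
    matrices = list(matrices)
    tables = list(cell_tables)
    if len(matrices) != len(tables) or not matrices:
        raise ValueError("need one cell table per dataset")
    genes0 = matrices[0].gene_symbols
    for nm in matrices[1:]:
        if not np.array_equal(nm.gene_symbols, genes0):
            raise ValueError("shared gene universe required; harmonize first")
    for nm, tab in zip(matrices, tables):
        if tab["subpop"].isna().any():
            raise ValueError(f"dataset {nm.dataset_id!r} has unannotated cells")
        if len(tab) != nm.n_cells:
            raise ValueError("cell table / matrix size mismatch")
    values = np.concatenate([nm.values for nm in matrices], axis=1)
    barcodes = np.concatenate(
        [
            np.array([f"{nm.dataset_id}:{b}" for b in nm.barcodes], dtype=object)
            for nm in matrices
        ]
    )
    meta = pd.concat(tables, ignore_index=True)
    atlas = NormalizedMatrix(
        values=values,
        gene_symbols=genes0.copy(),
        barcodes=barcodes,
        dataset_id="meta-atlas",
        scale_factor=matrices[0].scale_factor,
    )
    return atlas, meta


def de_vs_reference(
    atlas: NormalizedMatrix,
    atlas_table: pd.DataFrame,
    reference: NormalizedMatrix,
    reference_table: pd.DataFrame,
    subpop: str,
) -> pd.DataFrame:
    """DE of an atlas subpopulation against the same subpopulation in the
    reference compartment (group 1 = atlas, group 2 = reference)."""
    if subpop not in set(reference_table["subpop"].dropna()):
        raise ValueError(f"subpopulation {subpop!r} absent from the reference compartment")
    return de_between_datasets(atlas, reference, atlas_table, reference_table, subpop)


def extract_signatures(
    atlas: NormalizedMatrix,
    atlas_table: pd.DataFrame,
    reference: NormalizedMatrix,
    reference_table: pd.DataFrame,
    subpops: Sequence[str],
) -> dict[str, pd.DataFrame]:
    """Per-subpopulation meta-signature: flagged DE genes vs the reference,
    with direction derived from the sign of logfc."""
    out: dict[str, pd.DataFrame] = {}
    for s in subpops:
        de = de_vs_reference(atlas, atlas_table, reference, reference_table, s)
        sig = de[de["de_flag"]].copy()
        sig["direction"] = np.where(sig["logfc"] > 0, "up", "down")
        out[s] = sig.reset_index(drop=True)
    return out


def link_functions(
    de: pd.DataFrame,
    fmap: FunctionMap,
    exclude: Sequence[str] = (),
) -> tuple[pd.DataFrame, list[str]]:
    """Chord edge list (function, gene, direction, logfc) for flagged DE genes.

    Excluded labels are dropped entirely; flagged genes with no mapped
    function are returned separately rather than silently lost.
    """
    excluded = set(exclude)
    flagged = de[de["de_flag"]]
    edges = []
    unmapped: list[str] = []
    for _, row in flagged.iterrows():
        g = str(row["gene"])
        funcs = fmap.mapping.get(g, set()) - excluded
        if not funcs:
            unmapped.append(g)
            continue
        direction = "up" if row["logfc"] > 0 else "down"
        for f in sorted(funcs):
            edges.append(
                {"function": f, "gene": g, "direction": direction, "logfc": float(row["logfc"])}
            )
    return pd.DataFrame(edges, columns=["function", "gene", "direction", "logfc"]), unmapped


def signatures_to_json(signatures: Mapping[str, pd.DataFrame], path: str) -> None:
    payload = {
        s: df[["gene", "logfc", "ratio", "p_adj", "direction"]].to_dict(orient="records")
        for s, df in signatures.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
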