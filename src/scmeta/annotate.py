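"""Marker-panel cluster annotation and subpopulation proportion tables.

Clusters are scored against a marker panel on scaled expression and
assigned by argmax with a margin rule; NK and T are merged into NKT after
assignment, mirroring the four merged immune groups (NK&T, myeloid,
plasma, B) used throughout the analysis.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corepipe import NormalizedMatrix, scale_genes

__all__ = [
    "DEFAULT_PANEL",
    "score_clusters",
    "assign_subpopulations",
    "proportions",
]

#: Default marker panel: lineage -> marker symbols.  FCGR3A appears in both
#: the NK and myeloid panels on purpose; co-markers disambiguate.
DEFAULT_PANEL: dict[str, tuple[str, ...]] = {
    "T": ("CD3D",),
    "NK": ("KLRF1", "FCGR3A"),
    "Myeloid": ("FCGR3A", "CD14"),
    "B": ("CD19",),
    "Plasma": ("SDC1",),
}

#: Post-assignment merge of fine lineages into the four reported groups.
MERGE_MAP = {"T": "NKT", "NK": "NKT", "Myeloid": "Myeloid", "B": "B", "Plasma": "Plasma"}

UNASSIGNED = "Unassigned"


def score_clusters(
    nm: NormalizedMatrix,
    cluster_labels: np.ndarray,
    panel: Mapping[str, Sequence[str]] = DEFAULT_PANEL,
    scaled: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cluster x lineage score matrix.

    The score for (cluster, lineage) is the mean over the cluster's cells
    of the mean scaled expression of that lineage's markers.  Raises if a
    panel marker is missing from the gene universe.
    """
    for lineage, markers in panel.items():
        if not markers:
            raise ValueError(f"empty marker set for {lineage!r}")
        missing = [m for m in markers if m not in set(nm.gene_symbols)]
        if missing:
            raise KeyError(f"markers absent from gene universe for {lineage!r}: {missing}")
    if scaled is None:
        scaled = scale_genes(nm)
    labels = np.asarray(cluster_labels)
    clusters = np.unique(labels)
    rows = {}
    for c in clusters:
        mask = labels == c
        rows[int(c)] = {
            lineage: float(
                np.mean([scaled[nm.gene_index(m), mask].mean() for m in markers])
            )
            for lineage, markers in panel.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def assign_subpopulations(
    scores: pd.DataFrame,
    cell_table: pd.DataFrame,
    cluster_labels: np.ndarray,
    min_margin: float = 0.25,
    override: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Assign each cluster (hence each cell) to a merged subpopulation.

    A cluster takes the argmax lineage if its margin over the runner-up is
    at least ``min_margin`` (inclusive); exact ties and sub-margin calls
    become ``Unassigned``.  NK and T merge into NKT.  ``override`` maps
    cluster id -> subpopulation and wins over the rule.
    """
    cluster_to_subpop: dict[int, str] = {}
    for c, row in scores.iterrows():
        vals = row.sort_values(ascending=False)
        if override and int(c) in override:
            cluster_to_subpop[int(c)] = override[int(c)]
            continue
        winner = str(vals.index[0])
        merged = MERGE_MAP.get(winner, winner)
        # the margin is against the best lineage that maps to a DIFFERENT
        # merged subpopulation (T vs NK compete for the same NKT call)
        rivals = [
            float(vals[l]) for l in vals.index if MERGE_MAP.get(str(l), str(l)) != merged
        ]
        top, runner = float(vals.iloc[0]), max(rivals) if rivals else -np.inf
        if np.isclose(top, runner) or (top - runner) < min_margin - 1e-12:
            cluster_to_subpop[int(c)] = UNASSIGNED
        else:
            cluster_to_subpop[int(c)] = merged

    out = cell_table.copy()
    labels = np.asarray(cluster_labels)
    out["cluster_id"] = pd.array(labels, dtype="Int64")
    out["subpop"] = pd.array([cluster_to_subpop[int(c)] for c in labels], dtype="string")
    return out


def proportions(cell_table: pd.DataFrame) -> pd.DataFrame:
    """Dataset x subpopulation counts and percentages.

    Percentages are over assigned cells; ``Unassigned`` is reported as its
    own column but excluded from the percentage denominator only if absent.
    """
    if cell_table["subpop"].isna().any():
        raise ValueError("subpopulations not assigned for all cells")
    counts = (
        cell_table.groupby(["dataset_id", "subpop"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    pct = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    counts.columns = [f"n_{c}" for c in counts.columns]
    pct.columns = [f"pct_{c}" for c in pct.columns]
    return pd.concat([counts, pct], axis=1)
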