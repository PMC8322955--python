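"""Synthetic multi-dataset scRNA-seq collections with known ground truth.

Counts follow a negative binomial (gamma-Poisson) law per gene and cell:

    mean = baseline_rate * marker_mult * uniform_batch * specific_batch * library_size

with gene-level dispersion drawn lognormally.  Batch effects come in two
flavours: *uniform* factors hit a gene in every cell of a dataset, while
*specific* factors hit a gene only in cells of one target subpopulation —
the distinction the difference-of-differences statistic is built to detect.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .ingest import CountMatrix, make_cell_table

__all__ = [
    "SUBPOPS",
    "SimConfig",
    "TruthTable",
    "generate_collection",
    "generate_reference_compartment",
    "write_fixture",
]

#: The four immune subpopulations, in canonical order.
SUBPOPS = ("NKT", "Myeloid", "Plasma", "B")

#: Named marker genes and the subpopulation(s) they are elevated in.
#: FCGR3A is deliberately shared between the NK and myeloid lineages.
PANEL_MARKERS: dict[str, tuple[str, ...]] = {
    "CD3D": ("NKT",),
    "KLRF1": ("NKT",),
    "FCGR3A": ("NKT", "Myeloid"),
    "CD14": ("Myeloid",),
    "CD19": ("B",),
    "SDC1": ("Plasma",),
}

DEFAULT_HOUSEKEEPING = ("ACTB", "GAPDH", "B2M", "RPL13A", "UBC", "TBP")
DEFAULT_CONTAMINANTS = ("ALB", "APOA1", "ORM1")
PAN_IMMUNE_GENE = "PTPRC"  # CD45; expressed in every immune cell


@dataclass
class SimConfig:
    """Parameters of a synthetic multi-dataset collection.

    ``subpop_proportions`` holds one probability vector over
    ``(NKT, Myeloid, Plasma, B)`` per dataset.  ``marker_effect`` is the
    fold-change multiplier applied to a marker gene in its own
    subpopulation; 1.0 plants no signal.  ``specific_effect_logfc``, when
    set, replaces the random subpopulation-specific factors with a fixed
    ``exp(logfc)`` multiplier in the datasets listed in
    ``specific_datasets`` (a controlled planted interaction for recovery
    tests).
    """

    n_datasets: int = 3
    cells_per_dataset: Sequence[int] = (1000, 800, 1200)
    n_genes: int = 1000
    subpop_proportions: Sequence[Sequence[float]] | None = None
    marker_effect: float = 4.0
    n_markers_per_subpop: int = 25
    batch_sigma_uniform: float = 0.0
    batch_sigma_specific: float = 0.0
    frac_specific_genes: float = 0.0
    specific_subpop: str = "Myeloid"
    specific_effect_logfc: float | None = None
    specific_datasets: Sequence[int] = (1,)
    libsize_logmean: float = float(np.log(5000.0))
    libsize_logsd: float = 0.35
    contamination_genes: Sequence[str] = DEFAULT_CONTAMINANTS
    contamination_rates: Sequence[float] | None = None
    housekeeping_genes: Sequence[str] = DEFAULT_HOUSEKEEPING
    nonliver_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.cells_per_dataset = tuple(int(c) for c in self.cells_per_dataset)
        if len(self.cells_per_dataset) != self.n_datasets:
            raise ValueError("cells_per_dataset length must equal n_datasets")
        if any(c < 1 for c in self.cells_per_dataset):
            raise ValueError("every dataset needs at least one cell")
        if self.subpop_proportions is None:
            # defaults inside the abundance ranges seen across liver immune
            # datasets; ranking NKT > Myeloid > Plasma > B in every dataset
            base = [(0.60, 0.25, 0.10, 0.05), (0.55, 0.28, 0.11, 0.06), (0.65, 0.22, 0.08, 0.05)]
            self.subpop_proportions = tuple(base[d % 3] for d in range(self.n_datasets))
        self.subpop_proportions = tuple(tuple(float(p) for p in row) for row in self.subpop_proportions)
        for row in self.subpop_proportions:
            if len(row) != len(SUBPOPS):
                raise ValueError(f"each proportion vector needs {len(SUBPOPS)} entries")
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError(f"subpopulation proportions must sum to 1, got {sum(row)}")
        if self.marker_effect < 1.0:
            raise ValueError("marker_effect must be >= 1")
        if self.specific_subpop not in SUBPOPS:
            raise ValueError(f"specific_subpop must be one of {SUBPOPS}")
        if self.contamination_rates is None:
            self.contamination_rates = tuple(0.0 for _ in range(self.n_datasets))
        self.contamination_rates = tuple(float(r) for r in self.contamination_rates)
        if len(self.contamination_rates) != self.n_datasets:
            raise ValueError("contamination_rates length must equal n_datasets")
        named = (
            len(PANEL_MARKERS)
            + 1
            + len(self.housekeeping_genes)
            + len(self.contamination_genes)
        )
        if self.n_genes < named + len(SUBPOPS) * self.n_markers_per_subpop:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {named} named genes plus "
                f"{len(SUBPOPS) * self.n_markers_per_subpop} marker slots"
            )


@dataclass
class TruthTable:
    """Ground truth of a generated collection.

    ``marker_of`` maps gene symbol -> tuple of subpopulations it is elevated
    in.  ``uniform_factors`` is (datasets x genes); ``specific_factors`` is
    (datasets x genes) with ``specific_target`` naming the one subpopulation
    each affected gene's factor applies to.
    """

    dataset_ids: tuple[str, ...]
    gene_symbols: np.ndarray
    cell_subpop: dict[str, np.ndarray]
    marker_of: dict[str, tuple[str, ...]]
    uniform_factors: np.ndarray
    specific_factors: np.ndarray
    specific_target: dict[str, str]
    true_proportions: dict[str, tuple[float, ...]]
    baseline_rate: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.uniform_factors)) or np.any(self.uniform_factors <= 0):
            raise ValueError("uniform batch factors must be finite and positive")
        if not np.all(np.isfinite(self.specific_factors)) or np.any(self.specific_factors <= 0):
            raise ValueError("specific batch factors must be finite and positive")


def _gene_universe(config: SimConfig) -> tuple[np.ndarray, dict[str, tuple[str, ...]]]:
    """Lay out the gene axis and the marker-of map (panel + synthetic markers)."""
    names: list[str] = list(PANEL_MARKERS)
    names.append(PAN_IMMUNE_GENE)
    names.extend(config.housekeeping_genes)
    names.extend(config.contamination_genes)
    marker_of = {g: subs for g, subs in PANEL_MARKERS.items()}
    counts = {s: sum(s in subs for subs in PANEL_MARKERS.values()) for s in SUBPOPS}
    serial = 1
    for sub in SUBPOPS:
        while counts[sub] < config.n_markers_per_subpop:
            g = f"MK{sub[:2].upper()}{serial:03d}"
            serial += 1
            names.append(g)
            marker_of[g] = (sub,)
            counts[sub] += 1
    while len(names) < config.n_genes:
        names.append(f"G{len(names):05d}")
    return np.array(names, dtype=object), marker_of


def _baseline_rates(config: SimConfig, genes: np.ndarray, marker_of, rng) -> np.ndarray:
    """Relative expression rates, normalized to sum 1 before multipliers."""
    rate = rng.lognormal(mean=0.0, sigma=1.2, size=len(genes))
    idx = {g: i for i, g in enumerate(genes)}
    # markers get solid mid-high baseline so the planted fold change survives
    # library-size normalization and the log1p transform
    for g in marker_of:
        rate[idx[g]] = rng.lognormal(mean=1.1, sigma=0.25)
    for g in config.housekeeping_genes:
        rate[idx[g]] = rng.lognormal(mean=2.3, sigma=0.05)
    rate[idx[PAN_IMMUNE_GENE]] = np.exp(2.5)
    for g in config.contamination_genes:
        rate[idx[g]] = rng.lognormal(mean=-1.0, sigma=0.2)
    return rate / rate.sum()


def _dispersions(config: SimConfig, genes: np.ndarray, rng) -> np.ndarray:
    theta = rng.lognormal(mean=np.log(10.0), sigma=0.5, size=len(genes))
    hk = np.isin(genes.astype(str), np.asarray(config.housekeeping_genes, dtype=str))
    theta[hk] = 500.0  # housekeeping: tight, near-Poisson
    return theta


def _batch_factors(config: SimConfig, genes: np.ndarray, marker_of, rate, rng):
    n_d, n_g = config.n_datasets, len(genes)
    uniform = np.ones((n_d, n_g))
    if config.batch_sigma_uniform > 0:
        uniform = np.exp(rng.normal(0.0, config.batch_sigma_uniform, size=(n_d, n_g)))
    specific = np.ones((n_d, n_g))
    specific_target: dict[str, str] = {}
    n_specific = int(round(config.frac_specific_genes * n_g))
    if n_specific > 0:
        protected = set(marker_of) | set(config.housekeeping_genes) | set(config.contamination_genes)
        protected.add(PAN_IMMUNE_GENE)
        eligible = np.array(
            [i for i, g in enumerate(genes) if g not in protected], dtype=int
        )
        # restrict to a mid-expression band: below it the log1p floor swallows
        # the planted interaction; above it the affected genes carry so much
        # of the library that their shift leaks into every other gene through
        # library-size normalization (relative abundance is zero-sum)
        lo, hi = np.quantile(rate[eligible], [0.45, 0.70])
        eligible = eligible[(rate[eligible] >= lo) & (rate[eligible] <= hi)]
        chosen = rng.choice(eligible, size=min(n_specific, len(eligible)), replace=False)
        for gi in chosen:
            specific_target[str(genes[gi])] = config.specific_subpop
        if config.specific_effect_logfc is not None:
            for d in config.specific_datasets:
                specific[d, chosen] = np.exp(config.specific_effect_logfc)
        elif config.batch_sigma_specific > 0:
            specific[:, chosen] = np.exp(
                rng.normal(0.0, config.batch_sigma_specific, size=(n_d, len(chosen)))
            )
    return uniform, specific, specific_target


def _sample_dataset(
    config: SimConfig,
    d: int,
    genes: np.ndarray,
    marker_of,
    rate: np.ndarray,
    theta: np.ndarray,
    uniform: np.ndarray,
    specific: np.ndarray,
    specific_target: dict[str, str],
    rng,
    dataset_id: str,
) -> tuple[CountMatrix, pd.DataFrame, np.ndarray]:
    n_cells = config.cells_per_dataset[d]
    props = np.asarray(config.subpop_proportions[d])
    subpop_idx = rng.choice(len(SUBPOPS), size=n_cells, p=props)
    subpops = np.array([SUBPOPS[i] for i in subpop_idx], dtype=object)
    libsize = rng.lognormal(config.libsize_logmean, config.libsize_logsd, size=n_cells)

    # per-gene per-subpop multiplier: marker effect and specific batch factor
    mult = np.ones((len(genes), len(SUBPOPS)))
    gidx = {g: i for i, g in enumerate(genes)}
    for g, subs in marker_of.items():
        for s in subs:
            mult[gidx[g], SUBPOPS.index(s)] *= config.marker_effect
    for g, s in specific_target.items():
        mult[gidx[g], SUBPOPS.index(s)] *= specific[d, gidx[g]]

    mean = rate[:, None] * uniform[d][:, None] * mult[:, subpop_idx] * libsize[None, :]
    lam = rng.gamma(shape=theta[:, None], scale=mean / theta[:, None])
    counts = rng.poisson(lam).astype(np.int64)

    if config.contamination_rates[d] > 0:
        for g in config.contamination_genes:
            counts[gidx[g], :] += rng.poisson(config.contamination_rates[d], size=n_cells)

    tags = np.full(n_cells, "liver", dtype=object)
    if config.nonliver_frac > 0:
        n_blood = int(round(config.nonliver_frac * n_cells))
        blood = rng.choice(n_cells, size=n_blood, replace=False)
        tags[blood] = "blood"
    barcodes = np.array(
        [f"{dataset_id}_{tags[i]}_{i:05d}" for i in range(n_cells)], dtype=object
    )
    cm = CountMatrix(counts, genes.copy(), barcodes, dataset_id=dataset_id)
    table = make_cell_table(barcodes, dataset_id, tissue_tags=tags)
    return cm, table, subpops


def generate_collection(
    config: SimConfig,
) -> tuple[list[CountMatrix], pd.DataFrame, TruthTable]:
    """Generate ``n_datasets`` count matrices plus cell metadata and ground truth.

    Fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes, marker_of = _gene_universe(config)
    rate = _baseline_rates(config, genes, marker_of, rng)
    theta = _dispersions(config, genes, rng)
    uniform, specific, specific_target = _batch_factors(config, genes, marker_of, rate, rng)

    matrices: list[CountMatrix] = []
    tables: list[pd.DataFrame] = []
    cell_subpop: dict[str, np.ndarray] = {}
    dataset_ids = tuple(f"DS{d}" for d in range(config.n_datasets))
    for d, ds_id in enumerate(dataset_ids):
        cm, table, subpops = _sample_dataset(
            config, d, genes, marker_of, rate, theta, uniform, specific,
            specific_target, rng, ds_id,
        )
        matrices.append(cm)
        tables.append(table)
        cell_subpop[ds_id] = subpops

    truth = TruthTable(
        dataset_ids=dataset_ids,
        gene_symbols=genes,
        cell_subpop=cell_subpop,
        marker_of=marker_of,
        uniform_factors=uniform,
        specific_factors=specific,
        specific_target=specific_target,
        true_proportions={
            ds: tuple(config.subpop_proportions[d]) for d, ds in enumerate(dataset_ids)
        },
        baseline_rate=rate,
    )
    return matrices, pd.concat(tables, ignore_index=True), truth


def generate_reference_compartment(
    config: SimConfig,
    shift_genes: Sequence[str] = (),
    shift_logfc: float = 0.0,
    shift_subpop: str | None = None,
    n_cells: int | None = None,
    dataset_id: str = "REF",
) -> tuple[CountMatrix, pd.DataFrame, np.ndarray]:
    """Generate a PBMC-like reference dataset sharing the collection's structure.

    ``shift_logfc`` is the *expected log fold change of the primary
    collection relative to this reference* for ``shift_genes``: the
    reference mean is multiplied by ``exp(-shift_logfc)``, so a negative
    value plants genes that read as downregulated (ratio <= 0.8) when the
    collection is compared against the reference.  ``shift_subpop`` limits
    the shift to one subpopulation's cells (None = all).

    Returns the count matrix, the cell table, and the true per-cell
    subpopulation labels.
    """
    rng = np.random.default_rng(config.seed)
    genes, marker_of = _gene_universe(config)
    rate = _baseline_rates(config, genes, marker_of, rng)
    theta = _dispersions(config, genes, rng)

    gset = set(genes.astype(str))
    unknown = [g for g in shift_genes if g not in gset]
    if unknown:
        raise ValueError(f"unknown shift genes: {unknown[:10]}")
    if shift_subpop is not None and shift_subpop not in SUBPOPS:
        raise ValueError(f"shift_subpop must be one of {SUBPOPS}")

    ref_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_919]))
    n = n_cells if n_cells is not None else config.cells_per_dataset[0]
    props = np.asarray(config.subpop_proportions[0])
    subpop_idx = ref_rng.choice(len(SUBPOPS), size=n, p=props)
    subpops = np.array([SUBPOPS[i] for i in subpop_idx], dtype=object)
    libsize = ref_rng.lognormal(config.libsize_logmean, config.libsize_logsd, size=n)

    mult = np.ones((len(genes), len(SUBPOPS)))
    gidx = {g: i for i, g in enumerate(genes)}
    for g, subs in marker_of.items():
        for s in subs:
            mult[gidx[g], SUBPOPS.index(s)] *= config.marker_effect
    shift_rows = np.array([gidx[g] for g in shift_genes], dtype=int)
    if len(shift_rows):
        if shift_subpop is None:
            mult[shift_rows, :] *= np.exp(-shift_logfc)
        else:
            mult[shift_rows, SUBPOPS.index(shift_subpop)] *= np.exp(-shift_logfc)

    mean = rate[:, None] * mult[:, subpop_idx] * libsize[None, :]
    lam = ref_rng.gamma(shape=theta[:, None], scale=mean / theta[:, None])
    counts = ref_rng.poisson(lam).astype(np.int64)
    barcodes = np.array([f"{dataset_id}_blood_{i:05d}" for i in range(n)], dtype=object)
    cm = CountMatrix(counts, genes.copy(), barcodes, dataset_id=dataset_id)
    table = make_cell_table(barcodes, dataset_id, tissue_tags=["blood"] * n)
    return cm, table, subpops


def write_fixture(
    matrices: Sequence[CountMatrix],
    table: pd.DataFrame,
    truth: TruthTable | None,
    out_dir: str,
) -> list[str]:
    """Write one MTX triplet subdirectory per dataset plus truth TSVs.

    Round-trips exactly through :func:`scmeta.ingest.read_counts`.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("empty dataset list")
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []
    for cm in matrices:
        sub = os.path.join(out_dir, cm.dataset_id)
        os.makedirs(sub, exist_ok=True)
        spio.mmwrite(
            os.path.join(sub, "matrix.mtx"),
            sparse.coo_matrix(cm.values),
            field="integer",
        )
        # mmwrite appends .mtx if missing; normalize the name
        if os.path.exists(os.path.join(sub, "matrix.mtx.mtx")):
            os.replace(os.path.join(sub, "matrix.mtx.mtx"), os.path.join(sub, "matrix.mtx"))
        pd.Series(cm.barcodes).to_csv(
            os.path.join(sub, "barcodes.tsv"), sep="\t", index=False, header=False
        )
        pd.Series(cm.gene_symbols).to_csv(
            os.path.join(sub, "features.tsv"), sep="\t", index=False, header=False
        )
        written.append(sub)
    table.to_csv(os.path.join(out_dir, "cells.tsv"), sep="\t", index=False)
    written.append(os.path.join(out_dir, "cells.tsv"))
    if truth is not None:
        rows = []
        for ds, subs in truth.cell_subpop.items():
            cm = next(m for m in matrices if m.dataset_id == ds)
            rows.append(pd.DataFrame({"barcode": cm.barcodes, "dataset_id": ds, "subpop": subs}))
        pd.concat(rows, ignore_index=True).to_csv(
            os.path.join(out_dir, "truth_cells.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            {
                "gene": list(truth.marker_of),
                "marker_of": ["|".join(s) for s in truth.marker_of.values()],
            }
        ).to_csv(os.path.join(out_dir, "truth_markers.tsv"), sep="\t", index=False)
        written.extend(
            [os.path.join(out_dir, "truth_cells.tsv"), os.path.join(out_dir, "truth_markers.tsv")]
        )
    return written
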