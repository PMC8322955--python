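"""Normalization, scaling, PCA, graph clustering, 2D embedding, MNN-shift
integration, and the cluster-agreement metric.

Normalization is the standard library-size log transform: for raw count
``x`` in a cell with library size ``L``, the normalized value is
``ln(1 + 10_000 * x / L)``.  Downstream scaling standardizes each gene to
mean 0 / variance 1 using the population (divide-by-n) SD convention,
clipped at +/-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .ingest import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "AnchorSet",
    "lognormalize",
    "scale_genes",
    "select_hvg",
    "reduce_pca",
    "build_graph_and_cluster",
    "embed_2d",
    "integrate",
    "cluster_agreement",
    "mixing_entropy",
]

SCALE_CLIP = 10.0


@dataclass
class NormalizedMatrix:
    """Genes x cells matrix of natural-log library-size-normalized expression."""

    values: np.ndarray
    gene_symbols: np.ndarray
    barcodes: np.ndarray
    dataset_id: str
    scale_factor: float = 10_000.0
    library_sizes: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, symbol: str) -> int:
        idx = np.flatnonzero(self.gene_symbols == symbol)
        if len(idx) == 0:
            raise KeyError(f"gene {symbol!r} not present in dataset {self.dataset_id!r}")
        return int(idx[0])

    def subset_cells(self, mask: np.ndarray) -> "NormalizedMatrix":
        mask = np.asarray(mask)
        return replace(
            self,
            values=self.values[:, mask],
            barcodes=self.barcodes[mask],
            library_sizes=None if self.library_sizes is None else self.library_sizes[mask],
        )


@dataclass
class AnchorSet:
    """Mutual-nearest-neighbor cell pairs across two datasets, in PC space."""

    pairs: np.ndarray  # (n_anchors, 2): row index in reference block, row index in query block
    scores: np.ndarray  # similarity = 1 / (1 + euclidean distance)
    reference_id: str
    query_id: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("anchor scores must be finite")


def lognormalize(cm: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """``ln(1 + scale_factor * x / L)`` per entry, with ``L`` the cell's total UMIs.

    Exactly invertible given the library sizes; zero counts map to zero.
    """
    lib = cm.library_sizes().astype(np.float64)
    zero = np.flatnonzero(lib == 0)
    if len(zero):
        raise ValueError(
            f"cells with zero library size cannot be normalized: "
            f"{[str(b) for b in cm.barcodes[zero[:5]]]}"
        )
    values = np.log1p(scale_factor * cm.values.astype(np.float64) / lib[None, :])
    return NormalizedMatrix(
        values=values,
        gene_symbols=cm.gene_symbols.copy(),
        barcodes=cm.barcodes.copy(),
        dataset_id=cm.dataset_id,
        scale_factor=float(scale_factor),
        library_sizes=lib,
    )


def scale_genes(values: np.ndarray | NormalizedMatrix, clip: float = SCALE_CLIP) -> np.ndarray:
    """Standardize each gene across cells to mean 0, variance 1 (population SD).

    Constant genes map to all zeros; output is clipped at ``+/-clip``.
    """
    v = values.values if isinstance(values, NormalizedMatrix) else np.asarray(values, dtype=np.float64)
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=0, keepdims=True)
    out = np.zeros_like(v, dtype=np.float64)
    nonconst = sd[:, 0] > 0
    out[nonconst] = (v[nonconst] - mu[nonconst]) / sd[nonconst]
    return np.clip(out, -clip, clip)


def select_hvg(nm: NormalizedMatrix, n_top: int = 2000, n_bins: int = 20) -> np.ndarray:
    """Indices of the top highly-variable genes by binned standardized dispersion.

    Dispersion = variance / mean of the log-normalized values, z-scored
    within mean-expression bins so that selection is not driven by
    abundance alone.
    """
    v = nm.values
    mean = v.mean(axis=1)
    var = v.var(axis=1, ddof=0)
    disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    expressed = np.flatnonzero(mean > 0)
    if len(expressed) <= n_top:
        return expressed
    bins = np.quantile(mean[expressed], np.linspace(0, 1, n_bins + 1))
    which = np.clip(np.digitize(mean[expressed], bins[1:-1]), 0, n_bins - 1)
    z = np.zeros(len(expressed))
    for b in range(n_bins):
        in_bin = which == b
        if in_bin.sum() < 2:
            continue
        d = disp[expressed][in_bin]
        sd = d.std(ddof=0)
        z[in_bin] = (d - d.mean()) / sd if sd > 0 else 0.0
    order = np.argsort(-z, kind="stable")
    return np.sort(expressed[order[:n_top]])


def reduce_pca(
    scaled: np.ndarray,
    n_components: int = 30,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA on a genes x cells scaled matrix.

    Returns (scores: cells x k, loadings: genes x k, explained_variance).
    ``n_components`` is truncated to ``min(genes, cells) - 1`` if needed.
    """
    x = np.asarray(scaled, dtype=np.float64).T  # cells x genes
    k = min(n_components, min(x.shape) - 1)
    if k < n_components:
        import warnings

        warnings.warn(
            f"n_components truncated from {n_components} to {k} for input {x.shape}",
            stacklevel=2,
        )
    pca = PCA(n_components=k, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(x)
    return scores, pca.components_.T, pca.explained_variance_


def _snn_edges(scores: np.ndarray, k_neighbors: int, prune: float = 1.0 / 15.0):
    """Shared-nearest-neighbor graph: Jaccard overlap of kNN sets, pruned."""
    n = scores.shape[0]
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    _, idx = nn.kneighbors(scores)
    neigh = [set(row) for row in idx]  # includes self
    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j == i or (min(i, j), max(i, j)) in seen:
                continue
            seen.add((min(i, j), max(i, j)))
            shared = len(neigh[i] & neigh[j])
            jac = shared / len(neigh[i] | neigh[j])
            if jac >= prune:
                edges.append((i, j))
                weights.append(jac)
    return edges, weights


def build_graph_and_cluster(
    scores: np.ndarray,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on an SNN graph of the PC scores.

    Labels are integers 0..C-1, renumbered by decreasing cluster size;
    deterministic under a fixed seed.
    """
    import igraph as ig
    import leidenalg

    scores = np.asarray(scores, dtype=np.float64)
    edges, weights = _snn_edges(scores, k_neighbors)
    g = ig.Graph(n=scores.shape[0], edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # renumber by size, ties by smallest original label, for stable output
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.lexsort((uniq, -counts))]
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(l)] for l in labels], dtype=int)


def embed_2d(scores: np.ndarray, seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """UMAP of the PC scores to 2D, deterministic under a fixed seed."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from umap import UMAP

        reducer = UMAP(
            n_components=2,
            n_neighbors=min(n_neighbors, scores.shape[0] - 1),
            random_state=seed,
        )
        return np.asarray(reducer.fit_transform(np.asarray(scores, dtype=np.float64)))


def _mutual_pairs(a: np.ndarray, b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Mutual nearest neighbors between two point sets; returns pairs + distances."""
    k_ab = min(k, b.shape[0])
    k_ba = min(k, a.shape[0])
    nn_b = NearestNeighbors(n_neighbors=k_ab).fit(b)
    d_ab, idx_ab = nn_b.kneighbors(a)  # for each a: k nearest in b
    nn_a = NearestNeighbors(n_neighbors=k_ba).fit(a)
    _, idx_ba = nn_a.kneighbors(b)  # for each b: k nearest in a
    back = [set(row) for row in idx_ba]
    pairs, dists = [], []
    for i in range(a.shape[0]):
        for col, j in enumerate(idx_ab[i]):
            if i in back[int(j)]:
                pairs.append((i, int(j)))
                dists.append(d_ab[i, col])
    return np.array(pairs, dtype=int).reshape(-1, 2), np.array(dists)


def integrate(
    matrices: Sequence[NormalizedMatrix],
    k_anchor: int = 5,
    n_components: int = 30,
    hvg_n: int = 2000,
    seed: int = 0,
) -> tuple[list[AnchorSet], np.ndarray, np.ndarray]:
    """Simplified anchor integration: MNN pairs in joint PC space drive a
    locally weighted correction of each non-reference dataset toward the
    first (reference) dataset.

    The normalized matrices themselves are never modified; corrections
    live in PC space.  Returns (anchor sets, corrected scores stacked over
    all cells in input order, dataset label per row).
    """
    matrices = list(matrices)
    if len(matrices) < 2:
        raise ValueError("integration requires at least 2 datasets")
    genes0 = matrices[0].gene_symbols
    for nm in matrices[1:]:
        if not np.array_equal(nm.gene_symbols, genes0):
            raise ValueError("datasets must share an identical gene axis; harmonize first")

    joint = np.concatenate([nm.values for nm in matrices], axis=1)
    ref_nm = NormalizedMatrix(
        joint, genes0, np.arange(joint.shape[1]).astype(object), dataset_id="joint"
    )
    hvg = select_hvg(ref_nm, n_top=hvg_n)
    scaled = scale_genes(joint[hvg])
    scores, _, _ = reduce_pca(scaled, n_components=n_components, seed=seed)

    sizes = [nm.n_cells for nm in matrices]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    blocks = [scores[offsets[i]: offsets[i + 1]] for i in range(len(matrices))]
    labels = np.concatenate(
        [np.full(sz, nm.dataset_id, dtype=object) for sz, nm in zip(sizes, matrices)]
    )

    corrected = [blocks[0].copy()]
    anchor_sets: list[AnchorSet] = []
    ref = blocks[0]
    for d in range(1, len(matrices)):
        qry = blocks[d]
        pairs, dists = _mutual_pairs(ref, qry, k_anchor)
        if len(pairs) == 0:
            raise ValueError(
                f"no mutual-nearest-neighbor anchors between {matrices[0].dataset_id!r} "
                f"and {matrices[d].dataset_id!r}; increase k_anchor"
            )
        anchor_sets.append(
            AnchorSet(
                pairs=pairs,
                scores=1.0 / (1.0 + dists),
                reference_id=matrices[0].dataset_id,
                query_id=matrices[d].dataset_id,
            )
        )
        diffs = ref[pairs[:, 0]] - qry[pairs[:, 1]]  # correction direction per anchor
        # anchors are weighted by a Gaussian kernel on the distance to the
        # anchor MIDPOINT: for identical datasets the mutual-pair families
        # (i,j)/(j,i) share a midpoint, so their opposite difference vectors
        # receive equal weight and cancel exactly
        mids = 0.5 * (ref[pairs[:, 0]] + qry[pairs[:, 1]])
        out_block = np.empty_like(qry)
        chunk = 2048
        for start in range(0, qry.shape[0], chunk):
            c = qry[start: start + chunk]
            dist = np.sqrt(((c[:, None, :] - mids[None, :, :]) ** 2).sum(axis=-1))
            sigma = np.maximum(dist.mean(axis=1, keepdims=True), 1e-12)
            w = np.exp(-0.5 * (dist / sigma) ** 2)
            w /= w.sum(axis=1, keepdims=True)
            out_block[start: start + chunk] = c + w @ diffs
        corrected.append(out_block)

    return anchor_sets, np.concatenate(corrected, axis=0), labels


def cluster_agreement(
    labels_a: np.ndarray, labels_b: np.ndarray
) -> tuple[dict[int, float], float]:
    """Agreement of clustering A with clustering B over the same cells.

    For each A-cluster, agreement is the percentage of its cells falling in
    its best-matching B-cluster (matching by overlap, so label renaming is
    a no-op).  Overall agreement is the cell-weighted mean.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    per_cluster: dict[int, float] = {}
    matched = 0
    for a in np.unique(labels_a):
        in_a = labels_a == a
        _, counts = np.unique(labels_b[in_a], return_counts=True)
        best = int(counts.max())
        per_cluster[int(a)] = 100.0 * best / int(in_a.sum())
        matched += best
    return per_cluster, 100.0 * matched / len(labels_a)


def mixing_entropy(scores: np.ndarray, dataset_labels: np.ndarray, k: int = 30) -> float:
    """Mean Shannon entropy (nats) of dataset labels among each cell's kNN.

    Higher values mean datasets interdigitate more in the embedding space —
    the standard evidence that integration removed a batch shift.
    """
    labels = np.asarray(dataset_labels)
    codes = np.unique(labels, return_inverse=True)[1]
    n = scores.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    _, idx = nn.kneighbors(scores)
    ent = np.empty(n)
    for i in range(n):
        neigh = codes[idx[i, 1:]]
        p = np.bincount(neigh, minlength=codes.max() + 1) / k
        p = p[p > 0]
        ent[i] = -(p * np.log(p)).sum()
    return float(ent.mean())
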