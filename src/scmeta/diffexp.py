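"""Differential expression and the difference-of-differences (DoD) statistic.

DE convention: per gene, ``mean1`` and ``mean2`` are the mean
log-normalized expression of the two groups, ``logfc = mean1 - mean2``
(natural-log scale, the literal difference-of-means — NOT log-of-means),
``ratio = exp(logfc)``, with a two-sided Wilcoxon rank-sum p-value and
Bonferroni correction over the genes tested.  A gene is flagged DE when
``ratio >= 1.25 or ratio <= 0.8`` AND ``p_adj < 0.05`` (inclusive ratio
boundaries, strict alpha).

The DoD statistic partitions between-dataset DE: for a subpopulation S and
datasets 1, 2 with group means m11 = mean(S, ds1), m12 = mean(rest, ds1),
m21 = mean(S, ds2), m22 = mean(rest, ds2),

    dod = (m11 - m12) - (m21 - m22)

tested with a four-group Welch contrast t-test (Welch-Satterthwaite df).
A uniform between-dataset shift cancels in dod; only
subpopulation-specific dataset effects survive.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corepipe import NormalizedMatrix

__all__ = [
    "rank_sum_test",
    "de_from_groups",
    "de_subpop_vs_rest",
    "de_between_datasets",
    "classify_de",
    "dod",
    "dod_explained_summary",
    "heatmap_matrix",
    "top_de_master_list",
]

RATIO_LOW = 0.8
RATIO_HIGH = 1.25
ALPHA = 0.05

#: Largest group size for which the exact rank-sum null is enumerated.
EXACT_MAX_N = 8


def _exact_ranksum_p(ranks: np.ndarray, n1: int) -> float:
    """Exact two-sided rank-sum p by dynamic programming over the rank multiset.

    Midranks are doubled to integers; the DP counts, for every subset size
    and doubled-rank sum, the number of ways to choose that subset, giving
    the exact permutation null even under ties.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    # dp[k][s] = number of size-k subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in r2:
        for k in range(n1 - 1, -1, -1):
            dp[k + 1, r:] += dp[k, : total + 1 - r]
    counts = dp[n1]
    denom = counts.sum()
    obs = int(r2[:n1].sum())
    mean2 = n1 * (len(r2) + 1)  # doubled-rank null mean
    dev = abs(obs - mean2)
    sums = np.arange(total + 1)
    extreme = np.abs(sums - mean2) >= dev - 1e-9
    return float(counts[extreme].sum() / denom)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two samples.

    Exact permutation enumeration (tie-aware) when both groups have at
    most ``EXACT_MAX_N`` observations; otherwise the normal approximation
    with tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        return _exact_ranksum_p(ranks, n1)
    w = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    diff = w - mu
    z = (diff - np.sign(diff) * 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _ranksum_p_matrix(values: np.ndarray, mask1: np.ndarray, mask2: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p per gene (rows) between two cell masks."""
    v = values[:, mask1 | mask2]
    m1 = mask1[mask1 | mask2]
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        x = values[:, mask1]
        y = values[:, mask2]
        return np.array([rank_sum_test(x[g], y[g]) for g in range(values.shape[0])])
    n = n1 + n2
    ranks = stats.rankdata(v, axis=1)
    w = ranks[:, m1].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    # tie correction per gene from sorted-row run lengths
    s = np.sort(v, axis=1)
    tie_term = np.empty(v.shape[0])
    for g in range(v.shape[0]):
        _, counts = np.unique(s[g], return_counts=True)
        tie_term[g] = (counts.astype(np.float64) ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    diff = w - mu
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (diff - np.sign(diff) * 0.5) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[~np.isfinite(z)] = 1.0  # all values tied: no evidence
    return np.minimum(p, 1.0)


def de_from_groups(
    values: np.ndarray,
    gene_symbols: np.ndarray,
    mask1: np.ndarray,
    mask2: np.ndarray,
) -> pd.DataFrame:
    """DE table between two cell groups of a log-normalized matrix."""
    mask1 = np.asarray(mask1, dtype=bool)
    mask2 = np.asarray(mask2, dtype=bool)
    mean1 = values[:, mask1].mean(axis=1)
    mean2 = values[:, mask2].mean(axis=1)
    logfc = mean1 - mean2
    p = _ranksum_p_matrix(values, mask1, mask2)
    m = values.shape[0]
    de = pd.DataFrame(
        {
            "gene": gene_symbols.astype(str),
            "mean1": mean1,
            "mean2": mean2,
            "logfc": logfc,
            "ratio": np.exp(logfc),
            "p": p,
            "p_adj": np.minimum(1.0, p * m),
        }
    )
    return classify_de(de)


def de_subpop_vs_rest(
    nm: NormalizedMatrix,
    cell_table: pd.DataFrame,
    subpop: str,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Wilcoxon DE of one subpopulation against all other cells of the dataset."""
    subs = cell_table["subpop"].to_numpy()
    mask1 = subs == subpop
    mask2 = ~mask1
    if mask1.sum() < min_cells:
        raise ValueError(
            f"subpopulation {subpop!r} has {int(mask1.sum())} cells "
            f"(< min_cells={min_cells}) in dataset {nm.dataset_id!r}"
        )
    if mask2.sum() < min_cells:
        raise ValueError(f"rest group too small in dataset {nm.dataset_id!r}")
    return de_from_groups(nm.values, nm.gene_symbols, mask1, mask2)


def de_between_datasets(
    nm1: NormalizedMatrix,
    nm2: NormalizedMatrix,
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    subpop: str,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Wilcoxon DE of the same subpopulation between two datasets."""
    if not np.array_equal(nm1.gene_symbols, nm2.gene_symbols):
        raise ValueError("shared gene universe required; harmonize first")
    m1 = table1["subpop"].to_numpy() == subpop
    m2 = table2["subpop"].to_numpy() == subpop
    if m1.sum() < min_cells or m2.sum() < min_cells:
        raise ValueError(f"subpopulation {subpop!r} too small in one of the datasets")
    joint = np.concatenate([nm1.values[:, m1], nm2.values[:, m2]], axis=1)
    mask1 = np.zeros(joint.shape[1], dtype=bool)
    mask1[: int(m1.sum())] = True
    return de_from_groups(joint, nm1.gene_symbols, mask1, ~mask1)


def classify_de(
    de: pd.DataFrame,
    ratio_low: float = RATIO_LOW,
    ratio_high: float = RATIO_HIGH,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Apply the dual-threshold DE call: ratio >= 1.25 or <= 0.8 (inclusive)
    AND Bonferroni-adjusted p strictly below alpha."""
    out = de.copy()
    ratio = out["ratio"].to_numpy(dtype=float)
    p_adj = out["p_adj"].to_numpy(dtype=float)
    out["de_flag"] = ((ratio >= ratio_high) | (ratio <= ratio_low)) & (p_adj < alpha)
    out["volcano_class"] = np.where(out["de_flag"], "DE", "non-DE")
    return out


def _group_stats(values: np.ndarray, mask: np.ndarray):
    sub = values[:, mask]
    n = sub.shape[1]
    if n < 2:
        raise ValueError("each DoD group needs at least 2 cells (variance undefined)")
    return sub.mean(axis=1), sub.var(axis=1, ddof=1), n


def dod(
    nm1: NormalizedMatrix,
    nm2: NormalizedMatrix,
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    subpop: str,
) -> pd.DataFrame:
    """Difference-of-differences table for one subpopulation between two datasets.

    ``dod_flag`` requires BOTH the between-dataset DE call for the gene
    (same subpopulation, datasets 1 vs 2) and a Bonferroni-significant DoD
    contrast.
    """
    if not np.array_equal(nm1.gene_symbols, nm2.gene_symbols):
        raise ValueError("shared gene universe required; harmonize first")
    s1 = table1["subpop"].to_numpy() == subpop
    s2 = table2["subpop"].to_numpy() == subpop
    for label, m in (("subpop ds1", s1), ("rest ds1", ~s1), ("subpop ds2", s2), ("rest ds2", ~s2)):
        if m.sum() < 2:
            raise ValueError(f"group {label!r} has fewer than 2 cells")

    m11, v11, n11 = _group_stats(nm1.values, s1)
    m12, v12, n12 = _group_stats(nm1.values, ~s1)
    m21, v21, n21 = _group_stats(nm2.values, s2)
    m22, v22, n22 = _group_stats(nm2.values, ~s2)

    delta1 = m11 - m12
    delta2 = m21 - m22
    d = delta1 - delta2
    comps = np.stack([v11 / n11, v12 / n12, v21 / n21, v22 / n22])
    se2 = comps.sum(axis=0)
    ns = np.array([n11, n12, n21, n22])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d / np.sqrt(se2)
        df = se2**2 / (comps**2 / (ns - 1)[:, None]).sum(axis=0)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = se2 == 0
    t[zero_var] = 0.0
    df[zero_var] = float(n11 + n12 + n21 + n22 - 4)
    p[zero_var] = 1.0

    m = nm1.n_genes
    de_between = de_between_datasets(nm1, nm2, table1, table2, subpop, min_cells=2)
    out = pd.DataFrame(
        {
            "gene": nm1.gene_symbols.astype(str),
            "delta1": delta1,
            "delta2": delta2,
            "dod": d,
            "t": t,
            "df": df,
            "p": p,
            "p_adj": np.minimum(1.0, p * m),
        }
    )
    out["de_flag"] = de_between["de_flag"].to_numpy()
    out["dod_flag"] = out["de_flag"] & (out["p_adj"] < ALPHA)
    return out


def dod_explained_summary(dod_table: pd.DataFrame) -> dict:
    """Count DE and DoD genes and the percentage of DE genes that are DoD.

    With zero DE genes the percentage is undefined and reported as None.
    """
    n_de = int(dod_table["de_flag"].sum())
    n_dod = int(dod_table["dod_flag"].sum())
    return {
        "n_de": n_de,
        "n_dod": n_dod,
        "pct_dod_of_de": (100.0 * n_dod / n_de) if n_de > 0 else None,
    }


def heatmap_matrix(
    matrices: Sequence[NormalizedMatrix],
    genes: Sequence[str],
    cell_tables: Sequence[pd.DataFrame],
    gene_groups: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes x cells z-score matrix with columns grouped by subpopulation.

    Each row is z-scored over ALL cells (pooled across datasets), not per
    group.  Returns (matrix, column metadata); genes absent from the
    shared universe raise with the offenders listed.
    """
    matrices = list(matrices)
    gene_arr = matrices[0].gene_symbols.astype(str)
    missing = [g for g in genes if g not in set(gene_arr)]
    if missing:
        raise KeyError(f"genes absent from universe: {missing}")
    joint = np.concatenate([nm.values for nm in matrices], axis=1)
    meta = pd.concat(list(cell_tables), ignore_index=True)
    order = np.argsort(meta["subpop"].to_numpy().astype(str), kind="stable")
    joint = joint[:, order]
    meta = meta.iloc[order].reset_index(drop=True)

    rows = np.array([int(np.flatnonzero(gene_arr == g)[0]) for g in genes])
    sub = joint[rows]
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    idx = pd.Index(list(genes), name="gene")
    mat = pd.DataFrame(z, index=idx, columns=meta["barcode"])
    if gene_groups is not None:
        mat.insert(0, "gene_group", list(gene_groups))
    return mat, meta


def top_de_master_list(
    tables: Sequence[pd.DataFrame],
    dataset_ids: Sequence[str],
    n_top: int = 10,
) -> pd.DataFrame:
    """Union of each dataset's top DE genes (by p_adj, then |logfc|), de-duplicated.

    Only flagged genes are eligible; provenance records which datasets
    contributed each gene.
    """
    seen: dict[str, list[str]] = {}
    for tab, ds in zip(tables, dataset_ids):
        flagged = tab[tab["de_flag"]].copy()
        flagged["abs_logfc"] = flagged["logfc"].abs()
        top = flagged.sort_values(
            by=["p_adj", "abs_logfc", "gene"], ascending=[True, False, True]
        ).head(n_top)
        for g in top["gene"]:
            seen.setdefault(str(g), []).append(str(ds))
    return pd.DataFrame(
        {
            "gene": list(seen),
            "datasets": ["|".join(v) for v in seen.values()],
            "n_datasets": [len(v) for v in seen.values()],
        }
    )
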