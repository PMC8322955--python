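"""Between-dataset concordance statistics: proportion chi-squared tests,
housekeeping-gene noise, pseudobulk correlation, rank-rank hypergeometric
overlap (RRHO), and top-k abundant-transcript agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corepipe import NormalizedMatrix

__all__ = [
    "ChiSquareResult",
    "RRHOGrid",
    "proportion_chisq",
    "housekeeping_noise",
    "pseudobulk",
    "correlate_pairwise",
    "rank_genes",
    "rrho",
    "topk_agreement",
]


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    label: str
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("chi-squared statistic must be >= 0")
        if self.df < 1:
            raise ValueError("df must be >= 1")


@dataclass
class RRHOGrid:
    """-log10 hypergeometric enrichment p over a grid of rank-cutoff pairs.

    ``grid[i, j]`` corresponds to cutting list 1 at ``thresholds_1[i]`` and
    list 2 at ``thresholds_2[j]``; the entry at the full-length cutoff pair
    is 0 by construction (complete overlap, p = 1).
    """

    thresholds_1: np.ndarray
    thresholds_2: np.ndarray
    grid: np.ndarray
    n_genes: int
    step: int
    metric: str = "sign(logfc) * -log10(p)"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.grid, index=self.thresholds_1, columns=self.thresholds_2)


def proportion_chisq(
    counts: pd.DataFrame,
    mode: str = "overall",
    continuity_correction: bool = False,
) -> list[ChiSquareResult]:
    """Chi-squared tests on a dataset x subpopulation count table.

    ``overall`` runs one full-contingency test; ``pairwise`` runs a 2x2
    (subpopulation vs rest) test for every dataset pair and subpopulation.
    Input must be counts, not percentages.  No Yates continuity correction
    by default.  Expected cells below 1 attach a warning, not an error.
    """
    tab = counts.to_numpy(dtype=float)
    if not np.allclose(tab, np.round(tab)):
        raise ValueError("proportion_chisq expects integer counts, not percentages")

    def _one(sub: np.ndarray, label: str) -> ChiSquareResult:
        stat, p, df, expected = stats.chi2_contingency(
            sub, correction=continuity_correction
        )
        warn = "expected cell < 1" if (expected < 1).any() else None
        return ChiSquareResult(float(stat), int(df), float(p), label, warn)

    results: list[ChiSquareResult] = []
    if mode == "overall":
        results.append(_one(tab, "overall"))
    elif mode == "pairwise":
        datasets = list(counts.index)
        subpops = list(counts.columns)
        for i in range(len(datasets)):
            for j in range(i + 1, len(datasets)):
                for s, sub in enumerate(subpops):
                    two = np.array(
                        [
                            [tab[i, s], tab[i].sum() - tab[i, s]],
                            [tab[j, s], tab[j].sum() - tab[j, s]],
                        ]
                    )
                    results.append(_one(two, f"{datasets[i]}-vs-{datasets[j]}:{sub}"))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return results


def housekeeping_noise(
    matrices: Sequence[NormalizedMatrix],
    hk_genes: Sequence[str],
    cell_masks: Sequence[np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Technical-noise audit on housekeeping genes across datasets.

    Per gene: one-way ANOVA of log-normalized expression across datasets
    (optionally within a subpopulation via ``cell_masks``), plus pairwise
    Welch t-tests Bonferroni-corrected over genes x pairs.  Returns
    (anova table, pairwise table, per-dataset mean summary).  Missing
    genes are skipped with a warning column rather than raising.
    """
    import warnings

    matrices = list(matrices)
    if cell_masks is None:
        cell_masks = [np.ones(nm.n_cells, dtype=bool) for nm in matrices]
    groups_per_gene: dict[str, list[np.ndarray]] = {}
    skipped = []
    for g in hk_genes:
        rows = []
        ok = True
        for nm, mask in zip(matrices, cell_masks):
            try:
                rows.append(nm.values[nm.gene_index(g), np.asarray(mask, dtype=bool)])
            except KeyError:
                ok = False
                break
        if ok:
            groups_per_gene[g] = rows
        else:
            skipped.append(g)
    if skipped:
        warnings.warn(f"housekeeping genes missing from some datasets, skipped: {skipped}")
    if not groups_per_gene:
        raise ValueError("no housekeeping gene present in all datasets")

    ids = [nm.dataset_id for nm in matrices]
    anova_rows, pair_rows = [], []
    n_pairs = len(ids) * (len(ids) - 1) // 2
    m_anova = len(groups_per_gene)
    m_pair = m_anova * n_pairs
    for g, groups in groups_per_gene.items():
        import warnings as _w

        with np.errstate(invalid="ignore", divide="ignore"), _w.catch_warnings():
            _w.simplefilter("ignore")
            f_val, p_val = stats.f_oneway(*groups)
        if not np.isfinite(f_val):  # constant input: fall back on group means
            means = [gr.mean() for gr in groups]
            f_val, p_val = (0.0, 1.0) if np.allclose(means, means[0]) else (np.inf, 0.0)
        anova_rows.append(
            {"gene": g, "F": float(f_val), "p": float(p_val),
             "p_adj": float(min(1.0, p_val * m_anova))}
        )
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                with np.errstate(invalid="ignore", divide="ignore"), _w.catch_warnings():
                    _w.simplefilter("ignore")
                    t, p = stats.ttest_ind(groups[i], groups[j], equal_var=False)
                if not np.isfinite(t):
                    t, p = 0.0, 1.0
                pair_rows.append(
                    {
                        "gene": g,
                        "pair": f"{ids[i]}-vs-{ids[j]}",
                        "t": float(t),
                        "p": float(p),
                        "p_adj": float(min(1.0, p * m_pair)),
                    }
                )
    summary = pd.DataFrame(
        {
            "dataset_id": ids,
            "mean_hk_expression": [
                float(np.mean([groups_per_gene[g][d].mean() for g in groups_per_gene]))
                for d in range(len(ids))
            ],
        }
    )
    return pd.DataFrame(anova_rows), pd.DataFrame(pair_rows), summary


def pseudobulk(nm: NormalizedMatrix, cell_mask: np.ndarray | None = None) -> pd.Series:
    """Per-gene arithmetic mean of log-normalized expression over a cell subset."""
    if cell_mask is None:
        cell_mask = np.ones(nm.n_cells, dtype=bool)
    cell_mask = np.asarray(cell_mask)
    if cell_mask.dtype == bool:
        if not cell_mask.any():
            raise ValueError("empty cell subset")
        sub = nm.values[:, cell_mask]
    else:
        if len(cell_mask) == 0:
            raise ValueError("empty cell subset")
        sub = nm.values[:, cell_mask]
    return pd.Series(sub.mean(axis=1), index=nm.gene_symbols.astype(str), name=nm.dataset_id)


def correlate_pairwise(v1: np.ndarray, v2: np.ndarray) -> dict:
    """Pearson/Spearman correlation plus linear and quadratic least-squares fits.

    Zero-variance input makes the correlations undefined; they are reported
    as ``None`` with a ``degenerate`` flag rather than silent NaN.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError("inputs must be 1-D of equal length")
    if len(v1) < 3:
        raise ValueError("need at least 3 points")
    out: dict = {"n": int(len(v1)), "degenerate": False}
    if v1.std() == 0 or v2.std() == 0:
        out.update(
            degenerate=True, pearson_r=None, spearman_rho=None,
            linear=None, quadratic=None,
        )
        return out
    out["pearson_r"] = float(stats.pearsonr(v1, v2).statistic)
    out["spearman_rho"] = float(stats.spearmanr(v1, v2).statistic)
    slope, intercept = np.polyfit(v1, v2, deg=1)
    out["linear"] = {"slope": float(slope), "intercept": float(intercept)}
    a, b, c = np.polyfit(v1, v2, deg=2)
    out["quadratic"] = {"a": float(a), "b": float(b), "c": float(c)}
    return out


def rank_genes(de: pd.DataFrame) -> pd.DataFrame:
    """Rank a DE table by ``sign(logfc) * -log10(p)``, descending.

    Rank 1 is the most upregulated gene.  Zero p-values are floored at the
    smallest positive float before the log; ties break by ``|logfc|`` then
    by symbol.
    """
    p = np.maximum(de["p"].to_numpy(dtype=float), np.finfo(float).tiny)
    metric = np.sign(de["logfc"].to_numpy(dtype=float)) * (-np.log10(p))
    ranked = de.assign(rank_metric=metric)
    ranked = ranked.sort_values(
        by=["rank_metric", "logfc", "gene"],
        ascending=[False, False, True],
        key=lambda col: col.abs() if col.name == "logfc" else col,
    ).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked


def rrho(
    list1: Sequence[str],
    list2: Sequence[str],
    step: int | None = None,
) -> RRHOGrid:
    """Rank-rank hypergeometric overlap of two complete rankings of the same genes.

    For each cutoff pair (i, j), the overlap ``k`` of the top-i of list 1
    with the top-j of list 2 is scored with the one-sided enrichment
    survival probability ``P(X >= k)`` for X hypergeometric(N, i, j); the
    grid holds ``-log10 p``.  Default step gives at most a 50 x 50 grid.
    """
    l1 = np.asarray(list1, dtype=object)
    l2 = np.asarray(list2, dtype=object)
    if set(l1) != set(l2) or len(l1) != len(l2):
        raise ValueError("the two lists must be complete rankings of the same gene universe")
    if len(set(l1)) != len(l1):
        raise ValueError("duplicate genes in ranking")
    n = len(l1)
    if step is None:
        step = max(1, n // 50)
    thresholds = np.arange(step, n + 1, step)
    if thresholds[-1] != n:
        thresholds = np.append(thresholds, n)

    pos2 = {g: i for i, g in enumerate(l2)}
    pos_of_l1 = np.array([pos2[g] for g in l1]) + 1  # 1-based rank in list 2
    grid = np.empty((len(thresholds), len(thresholds)))
    for a, i in enumerate(thresholds):
        prefix = pos_of_l1[:i]
        k = (prefix[:, None] <= thresholds[None, :]).sum(axis=0)
        p = stats.hypergeom.sf(k - 1, n, i, thresholds)
        grid[a, :] = -np.log10(np.clip(p, 1e-320, 1.0))
    return RRHOGrid(
        thresholds_1=thresholds.copy(),
        thresholds_2=thresholds.copy(),
        grid=grid,
        n_genes=n,
        step=int(step),
    )


def topk_agreement(
    reference: NormalizedMatrix,
    other: NormalizedMatrix,
    ref_mask: np.ndarray,
    other_mask: np.ndarray,
    k: int = 100,
) -> dict:
    """Agreement of the top-k most abundant transcripts within a subpopulation.

    Abundance is the normalized pseudobulk mean; returns the intersection
    size and both gene lists.
    """
    if not np.array_equal(reference.gene_symbols, other.gene_symbols):
        raise ValueError("shared gene universe required; harmonize first")
    if reference.n_genes < k:
        raise ValueError(f"fewer than k={k} genes available")
    top_ref = pseudobulk(reference, ref_mask).nlargest(k).index.tolist()
    top_other = pseudobulk(other, other_mask).nlargest(k).index.tolist()
    inter = set(top_ref) & set(top_other)
    return {
        "k": k,
        "n_matched": len(inter),
        "reference_top": top_ref,
        "other_top": top_other,
        "matched": sorted(inter),
    }
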