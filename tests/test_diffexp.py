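import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from scmeta import corepipe, diffexp
from scmeta.corepipe import NormalizedMatrix
from scmeta.diffexp import (
    classify_de,
    de_between_datasets,
    de_from_groups,
    de_subpop_vs_rest,
    dod,
    dod_explained_summary,
    heatmap_matrix,
    rank_sum_test,
    top_de_master_list,
)
from scmeta.ingest import make_cell_table
from scmeta.simdata import SimConfig, generate_collection
from tests.conftest import truth_tables


def brute_force_ranksum_p(x, y):
    """Independent oracle: enumerate every assignment of the pooled ranks."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2.0
    dev = abs(obs - mean)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - mean) >= dev - 1e-9:
            hits += 1
    return hits / total


class TestRankSumExactness:
    @pytest.mark.parametrize("seed", range(10))
    def test_ties_against_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 9, 2)
        x = rng.integers(0, 4, n1).astype(float)
        y = rng.integers(0, 5, n2).astype(float)
        assert rank_sum_test(x, y) == pytest.approx(brute_force_ranksum_p(x, y), abs=1e-9)

    @given(
        st.lists(st.integers(0, 6), min_size=2, max_size=7),
        st.lists(st.integers(0, 6), min_size=2, max_size=7),
    )
    @settings(max_examples=30, deadline=None)
    def test_property_matches_enumeration(self, xs, ys):
        x, y = np.array(xs, float), np.array(ys, float)
        assert rank_sum_test(x, y) == pytest.approx(brute_force_ranksum_p(x, y), abs=1e-9)

    def test_continuous_matches_scipy_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.normal(size=6), rng.normal(size=8)
            expected = stats.mannwhitneyu(x, y, method="exact", alternative="two-sided").pvalue
            assert rank_sum_test(x, y) == pytest.approx(expected, abs=1e-12)

    def test_all_tied_p_one(self):
        assert rank_sum_test(np.ones(5), np.ones(6)) == 1.0
        assert rank_sum_test(np.ones(60), np.ones(60)) == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_sum_test(np.array([]), np.ones(3))


def nm_from(values, dataset_id="DS"):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        values,
        np.array([f"G{i}" for i in range(values.shape[0])], dtype=object),
        np.array([f"{dataset_id}_{j}" for j in range(values.shape[1])], dtype=object),
        dataset_id,
    )


def table_with(subpops, dataset_id="DS"):
    t = make_cell_table([f"{dataset_id}_{j}" for j in range(len(subpops))], dataset_id)
    t["subpop"] = pd.array(subpops, dtype="string")
    return t


class TestDESubpopVsRest:
    def test_null_simulation_flags(self):
        rng = np.random.default_rng(2)
        v = np.log1p(rng.poisson(2.0, (1000, 200)).astype(float))
        nm = nm_from(v)
        t = table_with(["NKT"] * 100 + ["B"] * 100)
        de = de_subpop_vs_rest(nm, t, "NKT")
        assert de["de_flag"].sum() <= 1
        frac = (de["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_identical_values_p_one(self):
        v = np.ones((3, 20))
        nm = nm_from(v)
        t = table_with(["NKT"] * 10 + ["B"] * 10)
        de = de_subpop_vs_rest(nm, t, "NKT")
        assert (de["p"] == 1.0).all()
        assert (de["logfc"] == 0.0).all()

    def test_planted_marker_power(self):
        """2-fold marker, 200 vs 600 cells: flagged with ratio > 1.25."""
        cfg = SimConfig(
            n_datasets=1, cells_per_dataset=(800,), n_genes=300, marker_effect=2.0,
            subpop_proportions=[(0.25, 0.35, 0.2, 0.2)], seed=6,
        )
        matrices, table, truth = generate_collection(cfg)
        nm = corepipe.lognormalize(matrices[0])
        (tab,) = truth_tables(matrices, table, truth)
        de = de_subpop_vs_rest(nm, tab, "NKT").set_index("gene")
        nkt_only = [g for g, subs in truth.marker_of.items() if subs == ("NKT",)]
        hits = de.loc[nkt_only]
        assert (hits["de_flag"] & (hits["ratio"] > 1.25)).mean() >= 0.9

    def test_too_few_cells_errors(self):
        nm = nm_from(np.ones((2, 5)))
        t = table_with(["NKT"] * 2 + ["B"] * 3)
        with pytest.raises(ValueError, match="min_cells"):
            de_subpop_vs_rest(nm, t, "NKT")


class TestDEBetweenDatasets:
    def test_self_copy_zero_flags(self):
        rng = np.random.default_rng(7)
        v = np.log1p(rng.poisson(3.0, (200, 100)).astype(float))
        nm1, nm2 = nm_from(v, "A"), nm_from(v, "B")
        t1, t2 = table_with(["NKT"] * 100, "A"), table_with(["NKT"] * 100, "B")
        de = de_between_datasets(nm1, nm2, t1, t2, "NKT")
        assert de["de_flag"].sum() == 0
        assert (de["p"] == 1.0).all()

    def test_planted_uniform_shift_flagged(self):
        rng = np.random.default_rng(8)
        v = np.log1p(rng.poisson(5.0, (300, 400)).astype(float))
        v2 = v.copy()
        shifted = rng.choice(300, 100, replace=False)
        v2[shifted] += np.log(1.5)
        de = de_between_datasets(
            nm_from(v, "A"), nm_from(v2, "B"),
            table_with(["NKT"] * 400, "A"), table_with(["NKT"] * 400, "B"),
            "NKT",
        )
        hit_rate = de.iloc[shifted]["de_flag"].mean()
        assert hit_rate >= 0.95
        assert de.drop(index=shifted)["de_flag"].sum() <= 2

    def test_swap_flips_logfc(self, two_dataset_pair):
        normed, tables, _ = two_dataset_pair
        d12 = de_between_datasets(normed[0], normed[1], tables[0], tables[1], "NKT")
        d21 = de_between_datasets(normed[1], normed[0], tables[1], tables[0], "NKT")
        np.testing.assert_allclose(d12["logfc"], -d21["logfc"], atol=1e-12)
        np.testing.assert_allclose(d12["p"], d21["p"], atol=1e-12)

    def test_missing_subpop_errors(self):
        nm = nm_from(np.ones((2, 4)))
        t1 = table_with(["NKT"] * 4, "DS")
        t2 = table_with(["B"] * 4, "DS")
        with pytest.raises(ValueError, match="too small"):
            de_between_datasets(nm, nm, t1, t2, "NKT")


class TestClassifyDE:
    def make(self, ratio, p_adj):
        return pd.DataFrame(
            {"gene": ["X"], "logfc": [np.log(ratio)], "ratio": [ratio], "p": [p_adj], "p_adj": [p_adj]}
        )

    def test_ratio_boundary_inclusive(self):
        de = classify_de(self.make(1.25, 0.049))
        assert bool(de["de_flag"].iloc[0])
        de = classify_de(self.make(0.8, 0.049))
        assert bool(de["de_flag"].iloc[0])

    def test_effect_size_gate(self):
        de = classify_de(self.make(1.10, 1e-30))
        assert not bool(de["de_flag"].iloc[0])

    def test_alpha_strict(self):
        de = classify_de(self.make(0.5, 0.05))
        assert not bool(de["de_flag"].iloc[0])

    def test_volcano_class_column(self):
        de = classify_de(self.make(2.0, 1e-5))
        assert de["volcano_class"].iloc[0] == "DE"


def welch_contrast_oracle(groups):
    """Independent four-sample contrast: dod, t, Welch-Satterthwaite df, p."""
    means = [np.mean(g) for g in groups]
    variances = [np.var(g, ddof=1) for g in groups]
    ns = [len(g) for g in groups]
    d = (means[0] - means[1]) - (means[2] - means[3])
    comps = [v / n for v, n in zip(variances, ns)]
    se2 = sum(comps)
    t = d / np.sqrt(se2)
    df = se2**2 / sum(c**2 / (n - 1) for c, n in zip(comps, ns))
    p = 2 * stats.t.sf(abs(t), df)
    return d, t, df, p


class TestDoD:
    def build(self, g11, g12, g21, g22):
        """One-gene DoD setup from four explicit value groups."""
        v1 = np.array([list(g11) + list(g12)], dtype=float)
        v2 = np.array([list(g21) + list(g22)], dtype=float)
        nm1, nm2 = nm_from(v1, "A"), nm_from(v2, "B")
        t1 = table_with(["NKT"] * len(g11) + ["B"] * len(g12), "A")
        t2 = table_with(["NKT"] * len(g21) + ["B"] * len(g22), "B")
        return dod(nm1, nm2, t1, t2, "NKT")

    def test_arithmetic(self):
        d = self.build((2.0, 2.0), (1.0, 1.0), (1.5, 1.5), (1.0, 1.0))
        assert d["delta1"].iloc[0] == pytest.approx(1.0)
        assert d["delta2"].iloc[0] == pytest.approx(0.5)
        assert d["dod"].iloc[0] == pytest.approx(0.5)

    def test_hand_computed_contrast(self):
        groups = [(3, 4, 5), (1, 2, 3), (2, 3, 4), (1, 2, 3)]
        d = self.build(*groups)
        exp_d, exp_t, exp_df, exp_p = welch_contrast_oracle([np.array(g, float) for g in groups])
        assert d["dod"].iloc[0] == pytest.approx(1.0)
        assert d["dod"].iloc[0] == pytest.approx(exp_d, abs=1e-12)
        assert d["t"].iloc[0] == pytest.approx(exp_t, abs=1e-12)
        assert d["df"].iloc[0] == pytest.approx(exp_df, abs=1e-12)
        assert d["p"].iloc[0] == pytest.approx(exp_p, abs=1e-12)

    def test_antisymmetry_under_swap(self, two_dataset_pair):
        normed, tables, _ = two_dataset_pair
        d12 = dod(normed[0], normed[1], tables[0], tables[1], "NKT")
        d21 = dod(normed[1], normed[0], tables[1], tables[0], "NKT")
        np.testing.assert_allclose(d12["dod"], -d21["dod"], atol=1e-12)
        np.testing.assert_allclose(d12["p"], d21["p"], atol=1e-12)

    def test_dod_flag_subset_of_de_flag(self, two_dataset_pair):
        normed, tables, _ = two_dataset_pair
        d = dod(normed[0], normed[1], tables[0], tables[1], "Myeloid")
        assert not (d["dod_flag"] & ~d["de_flag"]).any()

    def test_group_too_small_errors(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            self.build((1.0,), (1.0, 2.0), (1.0, 2.0), (1.0, 2.0))

    def test_bonferroni_monotone(self, two_dataset_pair):
        normed, tables, _ = two_dataset_pair
        d = dod(normed[0], normed[1], tables[0], tables[1], "NKT")
        assert (d["p_adj"] >= d["p"] - 1e-15).all()
        assert (d["p_adj"] <= 1.0).all()


class TestDoDRegimes:
    def test_uniform_vs_specific_separation(self):
        """Uniform batch: DoD type-I ~5%, pct explained <=10%; specific ln(2)
        effects: sensitivity >= 0.8 and pct explained clearly higher."""
        base = dict(
            n_datasets=2, cells_per_dataset=(1000, 1000), n_genes=800,
            marker_effect=1.0, batch_sigma_uniform=0.3,
        )
        cfg_u = SimConfig(**base, seed=11)
        matrices, table, truth = generate_collection(cfg_u)
        normed = [corepipe.lognormalize(m) for m in matrices]
        tabs = truth_tables(matrices, table, truth)
        d_u = dod(normed[0], normed[1], tabs[0], tabs[1], "Myeloid")
        s_u = dod_explained_summary(d_u)
        assert 0.03 <= (d_u["p"] < 0.05).mean() <= 0.07
        assert s_u["n_de"] > 50
        assert s_u["pct_dod_of_de"] <= 10.0

        cfg_s = SimConfig(
            **base, frac_specific_genes=0.2, specific_subpop="Myeloid",
            specific_effect_logfc=np.log(2), specific_datasets=(1,), seed=11,
        )
        matrices, table, truth = generate_collection(cfg_s)
        normed = [corepipe.lognormalize(m) for m in matrices]
        tabs = truth_tables(matrices, table, truth)
        d_s = dod(normed[0], normed[1], tabs[0], tabs[1], "Myeloid")
        planted = d_s["gene"].isin(set(truth.specific_target)).to_numpy()
        sensitivity = (d_s.loc[planted, "p_adj"] < 0.05).mean()
        assert sensitivity >= 0.8
        s_s = dod_explained_summary(d_s)
        assert s_s["pct_dod_of_de"] > 25.0
        # planted genes dominate the DoD-significant set
        dod_set = d_s[d_s["p_adj"] < 0.05]
        assert dod_set["gene"].isin(set(truth.specific_target)).mean() >= 0.8


class TestExplainedSummary:
    def test_no_de_undefined(self):
        t = pd.DataFrame({"de_flag": [False, False], "dod_flag": [False, False]})
        s = dod_explained_summary(t)
        assert s["n_de"] == 0 and s["pct_dod_of_de"] is None

    def test_all_de_also_dod(self):
        t = pd.DataFrame({"de_flag": [True, True], "dod_flag": [True, True]})
        assert dod_explained_summary(t)["pct_dod_of_de"] == 100.0


class TestHeatmapMatrix:
    def test_constant_gene_zero_row(self):
        nm = nm_from(np.vstack([np.ones(6), np.arange(6.0)]))
        t = table_with(["B"] * 3 + ["NKT"] * 3)
        mat, _ = heatmap_matrix([nm], ["G0", "G1"], [t])
        np.testing.assert_array_equal(mat.loc["G0"].to_numpy(dtype=float), 0.0)

    def test_rows_standardized(self):
        rng = np.random.default_rng(12)
        nm = nm_from(rng.exponential(size=(5, 40)))
        t = table_with(["B"] * 20 + ["NKT"] * 20)
        mat, _ = heatmap_matrix([nm], [f"G{i}" for i in range(5)], [t])
        z = mat.to_numpy(dtype=float)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-10)

    def test_marker_block_structure(self, small_normalized):
        normed, tables, truth = small_normalized
        markers = [g for g, subs in truth.marker_of.items() if subs == ("NKT",)][:5]
        mat, meta = heatmap_matrix(normed, markers, tables)
        z = mat.to_numpy(dtype=float)
        in_block = (meta["subpop"] == "NKT").to_numpy()
        assert z[:, in_block].mean() > 0 > z[:, ~in_block].mean()

    def test_absent_gene_listed(self, small_normalized):
        normed, tables, _ = small_normalized
        with pytest.raises(KeyError, match="NOPE"):
            heatmap_matrix(normed, ["NOPE"], tables)

    def test_columns_grouped_by_subpop(self, small_normalized):
        normed, tables, _ = small_normalized
        mat, meta = heatmap_matrix(normed, ["CD3D"], tables)
        subs = meta["subpop"].to_numpy().astype(str)
        assert (np.sort(subs) == subs).all()


class TestMasterList:
    def de_table(self, genes, p_adj, flags):
        return pd.DataFrame(
            {"gene": genes, "logfc": [1.0] * len(genes), "p_adj": p_adj, "de_flag": flags}
        )

    def test_identical_tables_length(self):
        t = self.de_table(["A", "B", "C"], [1e-5, 1e-4, 1e-3], [True] * 3)
        out = top_de_master_list([t, t, t], ["D1", "D2", "D3"], n_top=2)
        assert len(out) == 2
        assert set(out["datasets"]) == {"D1|D2|D3"}

    def test_disjoint_top_sets(self):
        t1 = self.de_table(["A", "B"], [1e-5, 1e-4], [True, True])
        t2 = self.de_table(["C", "D"], [1e-5, 1e-4], [True, True])
        t3 = self.de_table(["E", "F"], [1e-5, 1e-4], [True, True])
        out = top_de_master_list([t1, t2, t3], ["D1", "D2", "D3"], n_top=2)
        assert len(out) == 6

    def test_planted_markers_once_in_union(self, small_normalized):
        normed, tables, truth = small_normalized
        des = [de_subpop_vs_rest(nm, t, "B") for nm, t in zip(normed, tables)]
        out = top_de_master_list(des, [nm.dataset_id for nm in normed], n_top=5)
        assert out["gene"].is_unique
        b_markers = {g for g, subs in truth.marker_of.items() if subs == ("B",)}
        assert len(set(out["gene"]) & b_markers) > 0


class TestOrderInvariance:
    def test_de_flag_invariant_to_cell_and_gene_order(self):
        rng = np.random.default_rng(13)
        v = np.log1p(rng.poisson(3.0, (50, 80)).astype(float))
        subs = np.array(["NKT"] * 40 + ["B"] * 40)
        nm = nm_from(v)
        de1 = de_subpop_vs_rest(nm, table_with(subs), "NKT")

        cperm = rng.permutation(80)
        gperm = rng.permutation(50)
        v2 = v[gperm][:, cperm]
        nm2 = NormalizedMatrix(
            v2,
            nm.gene_symbols[gperm],
            np.array([f"P_{j}" for j in range(80)], dtype=object),
            "DS",
        )
        de2 = de_subpop_vs_rest(nm2, table_with(subs[cperm]), "NKT")
        merged = de1.set_index("gene").join(de2.set_index("gene"), rsuffix="_p")
        np.testing.assert_allclose(merged["p"], merged["p_p"], atol=1e-12)
        assert (merged["de_flag"] == merged["de_flag_p"]).all()
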