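"""Coexpression core: correlation, adjacency, TOM, clustering, modules."""

import numpy as np
import pandas as pd
import pytest

import coexnet as cx
from conftest import brute_force_tom, random_adjacency


def matrix_from_rows(rows):
    values = pd.DataFrame(
        rows, index=[f"g{i}" for i in range(1, len(rows) + 1)],
        columns=[f"s{j}" for j in range(1, len(rows[0]) + 1)],
    ).astype(float)
    meta = pd.DataFrame(
        {"condition": ["c"] * len(rows[0]),
         "replicate": list(range(1, len(rows[0]) + 1))},
        index=pd.Index(values.columns, name="sample"),
    )
    return cx.ExpressionMatrix(values, meta)


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),
        ],
    )
    def test_known_pairs(self, x, y, expected):
        corr = cx.pearson_matrix(matrix_from_rows([list(x), list(y)]))
        assert corr.r[0, 1] == pytest.approx(expected, abs=1e-12)
        np.testing.assert_array_equal(np.diag(corr.r), 1.0)

    def test_constant_gene_rejected_with_instruction(self):
        m = matrix_from_rows([[1, 1, 1], [1, 2, 3]])
        with pytest.raises(ValueError, match="drop_constant_genes"):
            cx.pearson_matrix(m)

    def test_too_few_samples_rejected(self):
        m = matrix_from_rows([[1, 2], [2, 1]])
        with pytest.raises(ValueError, match="3 samples"):
            cx.pearson_matrix(m)


class TestSignedAdjacency:
    @pytest.mark.parametrize(
        "r, beta, expected",
        [(1.0, 1, 1.0), (1.0, 7, 1.0), (-1.0, 1, 0.0), (-1.0, 5, 0.0),
         (0.6, 2, 0.64)],
    )
    def test_transform(self, r, beta, expected):
        corr = cx.CorrelationMatrix(["a", "b"], np.array([[1.0, r], [r, 1.0]]))
        adj = cx.signed_adjacency(corr, beta)
        assert adj.a[0, 1] == pytest.approx(expected, abs=1e-12)
        assert adj.a[0, 0] == 1.0

    def test_bad_beta_rejected(self):
        corr = cx.CorrelationMatrix(["a", "b"], np.eye(2))
        with pytest.raises(ValueError, match="beta"):
            cx.signed_adjacency(corr, 0)

    def test_entries_bounded(self):
        rng = np.random.default_rng(0)
        r = np.clip((lambda m: (m + m.T) / 2)(rng.uniform(-1, 1, (15, 15))), -1, 1)
        np.fill_diagonal(r, 1.0)
        corr = cx.CorrelationMatrix([f"g{i}" for i in range(15)], r)
        for beta in (1, 3, 9):
            a = cx.signed_adjacency(corr, beta).a
            assert a.min() >= 0 and a.max() <= 1


class TestScaleFreeFit:
    def _two_pass_oracle(self, a, n_bins=10):
        """Independent reimplementation of the binned log-log regression."""
        k = a.sum(axis=1) - 1.0
        edges = np.linspace(k.min(), k.max(), n_bins + 1)
        which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
        pts = []
        for b in range(n_bins):
            sel = k[which == b]
            if len(sel) and sel.mean() > 0:
                pts.append((np.log10(sel.mean()), np.log10(len(sel) / len(k))))
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        sl = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        r2 = (
            ((x - x.mean()) * (y - y.mean())).sum() ** 2
            / ((x - x.mean()) ** 2).sum()
            / ((y - y.mean()) ** 2).sum()
        )
        return r2 * (-np.sign(sl))

    def test_matches_independent_oracle_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = cx.AdjacencyMatrix(
                [f"g{i}" for i in range(200)], random_adjacency(rng, 200)
            )
            fit = cx.scale_free_fit(a)
            assert fit.signed_r2 == pytest.approx(self._two_pass_oracle(a.a),
                                                  abs=1e-10)

    def test_uniform_degree_flags_degenerate(self):
        a = cx.AdjacencyMatrix(["a", "b", "c"], np.full((3, 3), 1.0))
        fit = cx.scale_free_fit(a)
        assert fit.degenerate and fit.signed_r2 == 0.0

    def test_collinear_negative_slope_scores_one(self):
        # two clean degree groups -> two bin points, exactly collinear
        a = np.eye(20)
        a[0, 1:] = a[1:, 0] = 0.9   # one strong hub
        adj = cx.AdjacencyMatrix([f"g{i}" for i in range(20)], a)
        fit = cx.scale_free_fit(adj)
        assert fit.signed_r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.slope < 0


class TestSoftPowerScan:
    def test_mean_connectivity_strictly_decreasing(self, default_design_run):
        table = default_design_run["scan"].table
        assert (np.diff(table["mean_k"].to_numpy()) < 0).all()

    def test_planted_scale_free_network_reaches_fit_target(self):
        corr = cx.scale_free_probe_correlation(seed=0)
        scan = cx.pick_soft_power(corr)
        assert scan.chosen_power is not None
        assert scan.chosen_power <= 50
        row = scan.table[scan.table["power"] == scan.chosen_power].iloc[0]
        assert row["signed_r2"] >= 0.8

    def test_unreachable_target_returns_none_with_full_scan(self, tiny_matrix):
        corr = cx.pearson_matrix(tiny_matrix)
        scan = cx.pick_soft_power(corr, candidates=range(1, 6), r2_target=1.01)
        assert scan.chosen_power is None
        assert len(scan.table) == 5

    def test_unsorted_candidates_rejected(self, tiny_matrix):
        corr = cx.pearson_matrix(tiny_matrix)
        with pytest.raises(ValueError, match="sorted"):
            cx.pick_soft_power(corr, candidates=[3, 1, 2])


class TestTOM:
    def test_complete_triangle(self):
        a = cx.AdjacencyMatrix(list("abc"), np.ones((3, 3)))
        tom = cx.topological_overlap(a)
        np.testing.assert_allclose(tom.tom, 1.0)

    def test_three_node_path(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 1.0
        a[1, 2] = a[2, 1] = 1.0
        tom = cx.topological_overlap(cx.AdjacencyMatrix(list("abc"), a))
        assert tom.tom[0, 2] == pytest.approx(0.5)  # (L=1 + a=0)/(1 + 1 - 0)

    def test_empty_graph_has_zero_overlap(self):
        tom = cx.topological_overlap(cx.AdjacencyMatrix(list("abc"), np.eye(3)))
        off = tom.tom[~np.eye(3, dtype=bool)]
        np.testing.assert_array_equal(off, 0.0)

    def test_matches_brute_force_on_random_adjacencies(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = random_adjacency(rng, 20)
            tom = cx.topological_overlap(
                cx.AdjacencyMatrix([f"g{i}" for i in range(20)], a)
            )
            np.testing.assert_allclose(tom.tom, brute_force_tom(a), atol=1e-10)

    def test_entries_in_unit_interval(self, default_design_run):
        tom = default_design_run["tom"].tom
        assert tom.min() >= 0 and tom.max() <= 1


class TestClusteringAndCut:
    def two_block_tom(self, n_per_block=50, within=0.1, between=0.9):
        n = 2 * n_per_block
        d = np.full((n, n), between)
        d[:n_per_block, :n_per_block] = within
        d[n_per_block:, n_per_block:] = within
        np.fill_diagonal(d, 0.0)
        return cx.TOMMatrix([f"g{i:03d}" for i in range(n)], 1.0 - d)

    def test_two_blocks_split_at_top(self):
        tom = self.two_block_tom()
        dend = cx.cluster_dendrogram(tom)
        assert dend.heights.max() == pytest.approx(0.9)
        assign = cx.dynamic_tree_cut(dend, min_module_size=30)
        assert assign.n_modules == 2
        labels = assign.labels
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1
        assert labels[0] != labels[50]

    def test_singleton_input_gives_trivial_tree(self):
        tom = cx.TOMMatrix(["only"], np.ones((1, 1)))
        dend = cx.cluster_dendrogram(tom)
        assert dend.merge.shape == (0, 4)
        assign = cx.dynamic_tree_cut(dend, min_module_size=1)
        assert assign.labels.tolist() == [1]

    def test_equal_distances_cluster_deterministically(self):
        d = np.full((10, 10), 0.5)
        np.fill_diagonal(d, 0.0)
        tom = cx.TOMMatrix([f"g{i}" for i in range(10)], 1.0 - d)
        t1 = cx.cluster_dendrogram(tom)
        t2 = cx.cluster_dendrogram(tom)
        np.testing.assert_array_equal(t1.merge, t2.merge)

    def test_oversized_min_module_size_unassigns_all(self):
        rng = np.random.default_rng(0)
        d = rng.random((20, 20))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tom = cx.TOMMatrix([f"g{i}" for i in range(20)], 1.0 - np.clip(d, 0, 1))
        dend = cx.cluster_dendrogram(tom)
        with pytest.warns(UserWarning, match="min_module_size"):
            assign = cx.dynamic_tree_cut(dend, min_module_size=21)
        assert set(assign.labels) == {0}

    def test_labels_partition_genes_and_sizes_sum(self, default_design_run):
        assign = default_design_run["assign"]
        assert len(assign.labels) == len(assign.gene_ids)
        assert sum(assign.module_sizes.values()) == len(assign.gene_ids)
        for label, size in assign.module_sizes.items():
            if label != 0:
                assert size >= 30

    def test_planted_recovery_at_default_design(self, default_design_run):
        from sklearn.metrics import adjusted_rand_score

        truth = default_design_run["truth"]
        matrix = default_design_run["matrix"]
        assign = default_design_run["assign"]
        ari = adjusted_rand_score(truth.labels_for(matrix.gene_ids),
                                  assign.labels)
        assert ari >= 0.8

    def test_newick_export_contains_all_leaves(self):
        tom = self.two_block_tom(n_per_block=3)
        nwk = cx.cluster_dendrogram(tom).to_newick()
        assert nwk.endswith(";")
        for gene in tom.gene_ids:
            assert gene in nwk


class TestRegulatorGroup:
    def test_planted_regulator_module_recovered(self, default_design_run):
        truth = default_design_run["truth"]
        assign = default_design_run["assign"]
        label, members = cx.regulator_group(assign, "xyr1")
        assert label != 0
        planted = set(truth.module_members(1))
        assert len(planted & set(members)) / len(members) >= 0.8

    def test_unassigned_regulator_warns(self):
        assign = cx.ModuleAssignment(["a", "b", "c"], np.array([0, 1, 1]))
        with pytest.warns(UserWarning, match="unassigned"):
            label, members = cx.regulator_group(assign, "a")
        assert label == 0

    def test_unknown_vs_filtered_regulator_distinguished(self):
        assign = cx.ModuleAssignment(["a", "b"], np.array([1, 1]))
        with pytest.raises(KeyError, match="unknown"):
            cx.regulator_group(assign, "nope")
        with pytest.raises(KeyError, match="filter"):
            cx.regulator_group(assign, "gone", filtered_ids=["gone"])
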