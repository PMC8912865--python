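import numpy as np
import pandas as pd
import pytest

import coexnet as cx


@pytest.fixture
def tiny_matrix():
    """3 genes x 6 samples, two conditions, handmade values."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
         [2.0, 4.0, 6.0, 8.0, 10.0, 12.0],
         [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]],
        index=["g1", "g2", "g3"],
        columns=["c1", "c2", "c3", "gl1", "gl2", "gl3"],
    )
    meta = pd.DataFrame(
        {"condition": ["cellulose"] * 3 + ["glucose"] * 3,
         "replicate": [1, 2, 3, 1, 2, 3]},
        index=pd.Index(values.columns, name="sample"),
    )
    return cx.ExpressionMatrix(values, meta)


@pytest.fixture(scope="session")
def default_design_run():
    """Full module-detection run at the default desk-scale design (seed 42)."""
    design = cx.SyntheticDesign(
        seed=42, regulator_assignments={"xyr1": 1, "cre1": 2}
    )
    matrix, truth = cx.generate_expression(design)
    matrix, _ = cx.filter_low_expression(matrix)
    matrix, _ = cx.drop_constant_genes(matrix)
    corr = cx.pearson_matrix(matrix)
    scan = cx.pick_soft_power(corr)
    beta = scan.chosen_power
    tom = cx.topological_overlap(cx.signed_adjacency(corr, beta))
    assign = cx.dynamic_tree_cut(cx.cluster_dendrogram(tom))
    return {
        "design": design, "matrix": matrix, "truth": truth, "corr": corr,
        "scan": scan, "beta": beta, "tom": tom, "assign": assign,
    }


@pytest.fixture(scope="session")
def zero_noise_run():
    """Zero-noise planted design: 3 modules x 10 genes, 30 samples."""
    design = cx.SyntheticDesign(
        n_modules=3, genes_per_module=10, n_background_genes=0,
        conditions=(("cellulose", 15), ("glucose", 15)),
        noise_sd=0.0, seed=7,
        regulator_assignments={"xyr1": 1},
    )
    matrix, truth = cx.generate_expression(design)
    corr = cx.pearson_matrix(matrix)
    tom = cx.topological_overlap(cx.signed_adjacency(corr, 30))
    assign = cx.dynamic_tree_cut(cx.cluster_dendrogram(tom), min_module_size=5)
    net = cx.build_hrr_network(corr)
    return {
        "design": design, "matrix": matrix, "truth": truth,
        "corr": corr, "assign": assign, "net": net,
    }


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap oracle (diagonal of a ignored)."""
    n = a.shape[0]
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (L + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return out


def random_adjacency(rng, n):
    """Random symmetric adjacency in [0, 1] with unit diagonal."""
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def enumerate_geodesics(graph, source, target):
    """Exhaustive minimal-path oracle: (distance, count) by DFS enumeration."""
    if source == target:
        return 0, 1
    best = [None]
    counts = {}

    def dfs(node, visited, length):
        if best[0] is not None and length > best[0]:
            return
        for nb in graph.neighbors(node):
            if nb == target:
                total = length + 1
                if best[0] is None or total < best[0]:
                    best[0] = total
                    counts.clear()
                    counts[total] = 1
                elif total == best[0]:
                    counts[total] += 1
            elif nb not in visited:
                dfs(nb, visited | {nb}, length + 1)

    dfs(source, {source}, 0)
    if best[0] is None:
        return None, 0
    return best[0], counts[best[0]]
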