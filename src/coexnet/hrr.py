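"""Highest-reciprocal-rank (HRR) coexpression networks.

For each gene, its correlation partners are ranked 1, 2, ... by descending
Pearson r. A pair (i, j) becomes an edge when r_ij passes the correlation
threshold (default 0.8) and the *worse* of the two directional ranks —
the HRR rank — does not exceed the rank cutoff (default 30, the 30
strongest edges per gene). Edges carry a band weight coding the rank
band: 1/5 for ranks 1-10, 1/15 for 11-20, 1/30 for 21-30; these weights
are export/visualization attributes only, path analyses treat the graph
as unweighted.

The threshold applies to positive r by default (coexpressed
neighborhoods); pass ``absolute=True`` to threshold |r| instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .network import CorrelationMatrix, ModuleAssignment

__all__ = [
    "band_weight",
    "directional_ranks",
    "build_hrr_network",
    "module_subnetwork",
    "edge_table",
    "write_graphml",
]

BAND_WEIGHTS = (1 / 5, 1 / 15, 1 / 30)


def band_weight(hrr_rank: int) -> float | None:
    """Band weight for an HRR rank: 1/5 (ranks 1-10), 1/15 (11-20), 1/30 (21-30).

    Ranks above 30 carry no weight (the edge is excluded from the network).
    """
    if hrr_rank < 1:
        raise ValueError(f"hrr_rank must be >= 1, got {hrr_rank}")
    if hrr_rank <= 10:
        return 1 / 5
    if hrr_rank <= 20:
        return 1 / 15
    if hrr_rank <= 30:
        return 1 / 30
    return None


def directional_ranks(c: CorrelationMatrix) -> np.ndarray:
    """Per-gene neighbor ranks by descending correlation.

    Returns an integer matrix R where R[i, j] is the rank (1 = strongest)
    of gene j among gene i's partners; ties are broken by lexicographic
    gene id, R[i, i] = 0.
    """
    n = len(c.gene_ids)
    lex = np.argsort(np.argsort(np.asarray(c.gene_ids, dtype=object)))
    ranks = np.zeros((n, n), dtype=int)
    for i in range(n):
        others = np.array([j for j in range(n) if j != i])
        # lexsort: last key is primary -> sort by -r, then by lex gene id
        order = others[np.lexsort((lex[others], -c.r[i, others]))]
        ranks[i, order] = np.arange(1, n)
    return ranks


def build_hrr_network(
    c: CorrelationMatrix,
    r_threshold: float = 0.8,
    max_rank: int = 30,
    absolute: bool = False,
    assign: ModuleAssignment | None = None,
    annotations=None,
) -> nx.Graph:
    """Build the global HRR graph from a correlation matrix.

    Edge (i, j) is kept iff r_ij >= r_threshold (|r_ij| when
    ``absolute=True``) and max(rank_i(j), rank_j(i)) <= max_rank. Each
    edge stores ``r``, ``hrr_rank`` and ``band_weight``; nodes store a
    ``module`` label when an assignment is given and a ``category`` /
    ``de_status`` when an annotation table is given.
    """
    n = len(c.gene_ids)
    ranks = directional_ranks(c)
    score = np.abs(c.r) if absolute else c.r
    g = nx.Graph()
    g.add_nodes_from(c.gene_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if score[i, j] < r_threshold:
                continue
            hrr = int(max(ranks[i, j], ranks[j, i]))
            if hrr > max_rank:
                continue
            w = band_weight(hrr)
            if w is None:
                continue
            g.add_edge(
                c.gene_ids[i],
                c.gene_ids[j],
                r=float(c.r[i, j]),
                hrr_rank=hrr,
                band_weight=w,
            )
    if assign is not None:
        labels = dict(zip(assign.gene_ids, assign.labels.tolist()))
        nx.set_node_attributes(
            g, {v: int(labels.get(v, 0)) for v in g.nodes}, "module"
        )
    if annotations is not None:
        nx.set_node_attributes(
            g, {v: annotations.category_of(v) for v in g.nodes}, "category"
        )
        nx.set_node_attributes(
            g, {v: annotations.de_status.get(v, "none") for v in g.nodes}, "de_status"
        )
    return g


def module_subnetwork(net: nx.Graph, assign: ModuleAssignment, label: int) -> nx.Graph:
    """Induced subgraph on the genes of one module; node metadata retained."""
    if label not in assign.module_sizes:
        raise KeyError(f"unknown module label {label}")
    members = [g for g in assign.members(label) if g in net]
    return net.subgraph(members).copy()


def edge_table(net: nx.Graph) -> pd.DataFrame:
    """Long-format edge list (gene_a, gene_b, r, hrr_rank, band_weight, modules)."""
    rows = []
    for u, v, d in sorted(net.edges(data=True), key=lambda e: (e[0], e[1])):
        a, b = sorted((u, v))
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "r": d.get("r", np.nan),
                "hrr_rank": d.get("hrr_rank", 0),
                "band_weight": d.get("band_weight", np.nan),
                "module_a": net.nodes[a].get("module", 0),
                "module_b": net.nodes[b].get("module", 0),
            }
        )
    cols = ["gene_a", "gene_b", "r", "hrr_rank", "band_weight", "module_a", "module_b"]
    return pd.DataFrame(rows, columns=cols)


def write_graphml(net: nx.Graph, path) -> None:
    """GraphML export suitable for Cytoscape-style visualization."""
    clean = net.copy()
    for _, d in clean.nodes(data=True):
        for k, v in list(d.items()):
            if v is None:
                d[k] = ""
    nx.write_graphml(clean, path)
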