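"""Graph topology around regulators: hubs, first neighbors, geodesics.

Shortest-path ("geodesic") analysis treats the HRR graph as unweighted:
distance is the minimal number of edges between two transcripts, and the
geodesic count is the number of distinct shortest paths, computed with the
standard breadth-first-search counting recurrence
count(v) = sum of count(u) over predecessors u at distance d(v) - 1.
For regulator -> target pairs at distance exactly 2 the middle
("transitive") transcripts are reported, since those are candidate relays
between a transcription factor and its indirect targets.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .network import ModuleAssignment

__all__ = [
    "GeodesicSummary",
    "NeighborReport",
    "degree_and_hubs",
    "first_neighbors",
    "bfs_geodesics",
    "geodesics",
    "transitive_transcripts",
    "regulator_cazyme_matrix",
]


@dataclass
class GeodesicSummary:
    """Shortest-path summary for one (source, target) pair.

    ``distance`` is None when the target is unreachable (or absent from
    the graph, see ``reason``); ``intermediates`` lists the middle nodes
    when the distance is exactly 2.
    """

    source: str
    target: str
    distance: int | None
    n_geodesics: int
    intermediates: list[str] = field(default_factory=list)
    reason: str = ""

    @property
    def reachable(self) -> bool:
        return self.distance is not None


@dataclass
class NeighborReport:
    """First neighbors of a focal transcript with their annotations."""

    node: str
    table: pd.DataFrame  # columns: gene, module, category, de_status
    n_modules: int


def degree_and_hubs(net: nx.Graph, top_k: int = 1) -> pd.DataFrame:
    """Degree table with hub flags.

    Hubs are all nodes whose degree falls in the ``top_k`` highest
    *distinct* degree values, so ties at the top are all reported. Rows
    are ordered by (degree descending, gene id).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    rows = sorted(net.degree(), key=lambda t: (-t[1], t[0]))
    degrees = [d for _, d in rows]
    top_values = sorted(set(degrees), reverse=True)[:top_k]
    df = pd.DataFrame(rows, columns=["gene", "degree"])
    df["is_hub"] = df["degree"].isin(top_values)
    return df


def first_neighbors(
    net: nx.Graph,
    node: str,
    assign: ModuleAssignment | None = None,
    annotations=None,
) -> NeighborReport:
    """All transcripts adjacent to ``node`` with module/category/DE metadata.

    Also reports the number of distinct modules the neighbors span — the
    breadth of a regulator's direct coexpression reach.
    """
    if node not in net:
        raise KeyError(f"node {node!r} not present in the network")
    rows = []
    for nb in sorted(net.neighbors(node)):
        module = None
        if assign is not None and nb in assign.gene_ids:
            module = assign.label_of(nb)
        elif "module" in net.nodes[nb]:
            module = net.nodes[nb]["module"]
        category = annotations.category_of(nb) if annotations is not None else None
        de = annotations.de_status.get(nb, "none") if annotations is not None else None
        rows.append({"gene": nb, "module": module, "category": category, "de_status": de})
    df = pd.DataFrame(rows, columns=["gene", "module", "category", "de_status"])
    modules = {r["module"] for r in rows if r["module"] is not None}
    return NeighborReport(node, df, len(modules))


def bfs_geodesics(net: nx.Graph, source: str) -> tuple[dict[str, int], dict[str, int]]:
    """Single-source BFS distances and shortest-path counts.

    Returns (distance, count) dicts over the reachable nodes; the counting
    recurrence accumulates, for each node, the counts of all its
    predecessors one BFS level up.
    """
    dist = {source: 0}
    count = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in net.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                count[v] = count[u]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                count[v] += count[u]
    return dist, count


def geodesics(net: nx.Graph, source: str, targets) -> list[GeodesicSummary]:
    """Geodesic distance and count from a source to each target.

    Targets absent from the graph are reported as unreachable with a
    reason rather than raising, so batch regulator->CAZyme scans keep
    going.
    """
    if source not in net:
        raise KeyError(f"source {source!r} not present in the network")
    dist, count = bfs_geodesics(net, source)
    out = []
    for t in targets:
        if t not in net:
            out.append(GeodesicSummary(source, t, None, 0, reason="absent from network"))
        elif t not in dist:
            out.append(GeodesicSummary(source, t, None, 0, reason="unreachable"))
        else:
            inter: list[str] = []
            if dist[t] == 2:
                inter = sorted(
                    u for u in net.neighbors(source) if net.has_edge(u, t)
                )
            out.append(GeodesicSummary(source, t, dist[t], count[t], inter))
    return out


def transitive_transcripts(net: nx.Graph, source: str, target: str):
    """Middle nodes of length-2 shortest paths between two transcripts.

    Returns (intermediates, distance); intermediates is empty unless the
    geodesic distance is exactly 2.
    """
    if target not in net:
        raise KeyError(f"target {target!r} not present in the network")
    summary = geodesics(net, source, [target])[0]
    return summary.intermediates, summary.distance


def regulator_cazyme_matrix(
    net: nx.Graph, regulators, cazyme_targets
) -> pd.DataFrame:
    """Geodesic length and count for every regulator x CAZyme-target pair.

    Long-format table (regulator, cazyme, distance, n_geodesics,
    reachable) ready for heatmap pivoting: the distance is the minimal
    number of edges from the regulator to the enzyme transcript, the
    count the number of distinct routes of that length.
    """
    regulators = list(regulators)
    cazyme_targets = list(cazyme_targets)
    if not regulators or not cazyme_targets:
        raise ValueError("regulator and CAZyme target lists must be non-empty")
    rows = []
    for reg in regulators:
        for s in geodesics(net, reg, cazyme_targets):
            rows.append(
                {
                    "regulator": reg,
                    "cazyme": s.target,
                    "distance": s.distance,
                    "n_geodesics": s.n_geodesics,
                    "reachable": s.reachable,
                }
            )
    return pd.DataFrame(
        rows, columns=["regulator", "cazyme", "distance", "n_geodesics", "reachable"]
    )
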