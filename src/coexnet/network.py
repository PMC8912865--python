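"""Signed weighted coexpression network core.

Pipeline: Pearson correlation -> soft-power (scale-free fit) selection ->
signed adjacency a_ij = ((1 + r_ij)/2)^beta -> topological overlap matrix
(TOM) -> average-linkage dendrogram on 1 - TOM -> adaptive tree cut into
modules -> regulator-group lookup.

The scale-free fit index is the R^2 of the regression of log10 frequency on
log10 connectivity over binned connectivities, signed by the negated slope
direction, so that a decreasing (power-law-like) degree distribution scores
positively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "TOMMatrix",
    "Dendrogram",
    "ModuleAssignment",
    "ScaleFreeFit",
    "SoftPowerScan",
    "pearson_matrix",
    "signed_adjacency",
    "scale_free_fit",
    "pick_soft_power",
    "topological_overlap",
    "cluster_dendrogram",
    "dynamic_tree_cut",
    "regulator_group",
]


@dataclass
class CorrelationMatrix:
    """Symmetric gene-gene Pearson correlation matrix, diagonal exactly 1."""

    gene_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.r.shape != (n, n):
            raise ValueError(f"correlation matrix shape {self.r.shape} != ({n}, {n})")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if np.abs(self.r).max() > 1 + 1e-12:
            raise ValueError("correlation entries outside [-1, 1]")


@dataclass
class AdjacencyMatrix:
    """Symmetric soft-thresholded adjacency in [0, 1], diagonal 1."""

    gene_ids: list[str]
    a: np.ndarray
    beta: int = 1

    def __post_init__(self) -> None:
        if self.a.min() < -1e-12 or self.a.max() > 1 + 1e-12:
            raise ValueError("adjacency entries outside [0, 1]")

    def connectivity(self) -> np.ndarray:
        """Node connectivity k_i = sum_{j != i} a_ij (diagonal excluded)."""
        return self.a.sum(axis=1) - np.diag(self.a)


@dataclass
class TOMMatrix:
    """Topological overlap similarity in [0, 1]; dissimilarity = 1 - tom."""

    gene_ids: list[str]
    tom: np.ndarray

    def __post_init__(self) -> None:
        if self.tom.min() < -1e-12 or self.tom.max() > 1 + 1e-12:
            raise ValueError("TOM entries outside [0, 1]")

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.tom


@dataclass
class Dendrogram:
    """Average-linkage merge tree over genes (scipy linkage encoding)."""

    gene_ids: list[str]
    merge: np.ndarray  # (n-1, 4) scipy linkage matrix

    @property
    def heights(self) -> np.ndarray:
        return self.merge[:, 2]

    def to_newick(self) -> str:
        """Newick-like text rendering of the tree, heights as branch lengths."""
        tree = to_tree(self.merge)

        def walk(node, parent_h):
            length = max(parent_h - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.gene_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


@dataclass
class ModuleAssignment:
    """Per-gene module labels; label 0 marks unassigned genes."""

    gene_ids: list[str]
    labels: np.ndarray
    variant: str = "tree-cut"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if (self.labels < 0).any():
            raise ValueError("module labels must be >= 0")
        if len(self.labels) != len(self.gene_ids):
            raise ValueError("labels and gene_ids length mismatch")

    @property
    def module_sizes(self) -> dict[int, int]:
        lab, cnt = np.unique(self.labels, return_counts=True)
        return {int(l): int(c) for l, c in zip(lab, cnt)}

    @property
    def n_modules(self) -> int:
        """Number of proper (non-zero) modules."""
        return len([l for l in set(self.labels.tolist()) if l != 0])

    def members(self, label: int) -> list[str]:
        if label not in self.module_sizes:
            raise KeyError(f"no module with label {label}")
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]

    def label_of(self, gene_id: str) -> int:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None
        return int(self.labels[i])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.gene_ids, "module": self.labels})


@dataclass
class ScaleFreeFit:
    signed_r2: float
    slope: float
    mean_k: float
    median_k: float
    max_k: float
    degenerate: bool = False


@dataclass
class SoftPowerScan:
    """Scale-free fit statistics per candidate soft power beta."""

    table: pd.DataFrame  # columns: power, signed_r2, slope, mean_k, median_k, max_k
    chosen_power: int | None
    r2_target: float


def pearson_matrix(m: ExpressionMatrix) -> CorrelationMatrix:
    """Pairwise Pearson correlation of gene expression profiles."""
    if m.n_samples < 3:
        raise ValueError(f"need >= 3 samples for correlation, got {m.n_samples}")
    arr = m.values.to_numpy(dtype=float)
    var = arr.var(axis=1)
    if (var == 0).any():
        bad = [g for g, v in zip(m.gene_ids, var) if v == 0][:5]
        raise ValueError(
            f"constant gene(s) present (e.g. {bad}); run drop_constant_genes first"
        )
    r = np.corrcoef(arr)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(m.gene_ids, r)


def signed_adjacency(c: CorrelationMatrix, beta: int) -> AdjacencyMatrix:
    """Signed-network soft threshold: a_ij = ((1 + r_ij)/2)^beta, a_ii = 1."""
    if int(beta) != beta or beta < 1:
        raise ValueError(f"beta must be an integer >= 1, got {beta}")
    a = ((1.0 + c.r) / 2.0) ** int(beta)
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(c.gene_ids, a, beta=int(beta))


def scale_free_fit(a: AdjacencyMatrix, n_bins: int = 10) -> ScaleFreeFit:
    """Scale-free topology fit of the adjacency connectivity distribution.

    Connectivities are binned into ``n_bins`` equal-width bins; the mean
    connectivity and the occupancy frequency of each non-empty bin enter a
    log10-log10 linear regression. signed_r2 = R^2 x (-sign(slope)).
    """
    k = a.connectivity()
    mean_k = float(k.mean())
    median_k = float(np.median(k))
    max_k = float(k.max())
    if np.ptp(k) == 0.0:
        return ScaleFreeFit(0.0, 0.0, mean_k, median_k, max_k, degenerate=True)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    n = len(k)
    for b in range(n_bins):
        mask = idx == b
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        mk = float(k[mask].mean())
        if mk <= 0:
            continue
        xs.append(np.log10(mk))
        ys.append(np.log10(cnt / n))
    if len(xs) < 2:
        return ScaleFreeFit(0.0, 0.0, mean_k, median_k, max_k, degenerate=True)
    xs, ys = np.asarray(xs), np.asarray(ys)
    x_var = float(((xs - xs.mean()) ** 2).sum())
    if x_var == 0.0:
        return ScaleFreeFit(0.0, 0.0, mean_k, median_k, max_k, degenerate=True)
    slope = float(((xs - xs.mean()) * (ys - ys.mean())).sum()) / x_var
    intercept = float(ys.mean()) - slope * float(xs.mean())
    resid = ys - (slope * xs + intercept)
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    signed = r2 * (-np.sign(slope)) if slope != 0 else 0.0
    return ScaleFreeFit(float(signed), float(slope), mean_k, median_k, max_k)


def pick_soft_power(
    c: CorrelationMatrix,
    candidates=tuple(range(1, 51)),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> SoftPowerScan:
    """Scan candidate powers; choose the smallest reaching the fit target.

    Returns the full scan even when no candidate reaches ``r2_target``
    (``chosen_power`` is then None).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate power list is empty")
    if candidates != sorted(candidates):
        raise ValueError("candidate powers must be sorted ascending")
    rows = []
    chosen = None
    for beta in candidates:
        fit = scale_free_fit(signed_adjacency(c, beta), n_bins=n_bins)
        rows.append(
            {
                "power": beta,
                "signed_r2": fit.signed_r2,
                "slope": fit.slope,
                "mean_k": fit.mean_k,
                "median_k": fit.median_k,
                "max_k": fit.max_k,
                "degenerate": fit.degenerate,
            }
        )
        if chosen is None and fit.signed_r2 >= r2_target:
            chosen = beta
    return SoftPowerScan(pd.DataFrame(rows), chosen, r2_target)


def topological_overlap(a: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap: TOM_ij = (L_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    L_ij = sum_u a_iu a_uj over u distinct from i and j counts shared
    neighborhood weight; k_i is connectivity excluding the diagonal.
    TOM_ii = 1.
    """
    a0 = a.a.copy()
    np.fill_diagonal(a0, 0.0)
    L = a0 @ a0
    k = a0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + a0) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TOMMatrix(a.gene_ids, tom)


def cluster_dendrogram(t: TOMMatrix) -> Dendrogram:
    """Average-linkage hierarchical clustering of the TOM dissimilarity."""
    n = len(t.gene_ids)
    if n == 1:
        return Dendrogram(t.gene_ids, np.empty((0, 4)))
    d = t.dissimilarity.copy()
    np.fill_diagonal(d, 0.0)
    condensed = squareform(np.clip((d + d.T) / 2.0, 0.0, None), checks=False)
    merge = linkage(condensed, method="average")
    return Dendrogram(t.gene_ids, merge)


def dynamic_tree_cut(
    dend: Dendrogram,
    min_module_size: int = 30,
    cut_height_quantile: float = 0.99,
    deep_split: int = 2,
) -> ModuleAssignment:
    """Adaptive top-down cut of the dendrogram into modules.

    The tree is cut at a fraction of its maximum merge height
    (``cut_height_quantile`` at the default ``deep_split`` of 2; higher
    deep_split lowers the cut and yields finer modules). Branches below
    the cut with at least ``min_module_size`` leaves become proper
    modules. Smaller branches are merged upward into a proper module when
    the dendrogram joins them unambiguously to exactly one module not far
    above the cut (within 75% of the remaining height range); branches
    that cannot be absorbed are labelled 0 (unassigned). Labels are
    renumbered 1, 2, ... by descending module size (ties by smallest
    member gene id), so label 1 is always the largest module.
    """
    if not 0 <= deep_split <= 3:
        raise ValueError(f"deep_split must be in 0..3, got {deep_split}")
    n = len(dend.gene_ids)
    if min_module_size > n:
        warnings.warn(
            f"min_module_size={min_module_size} exceeds leaf count {n}; "
            "all genes left unassigned",
            stacklevel=2,
        )
        return ModuleAssignment(dend.gene_ids, np.zeros(n, dtype=int))
    variant = f"tree-cut(q={cut_height_quantile:.3g},ds={deep_split})"
    if n == 1 or len(dend.merge) == 0:
        return ModuleAssignment(
            dend.gene_ids, np.ones(n, dtype=int) if min_module_size <= 1 else
            np.zeros(n, dtype=int), variant=variant,
        )
    h_max = float(dend.heights.max())
    q_eff = 1.0 - (1.0 - cut_height_quantile) * (1.0 + (deep_split - 2) / 4.0)
    cut = q_eff * h_max
    labels = np.asarray(fcluster(dend.merge, t=cut, criterion="distance"), dtype=int)
    sizes = {int(l): int(c) for l, c in zip(*np.unique(labels, return_counts=True))}

    # absorb small branches that join exactly one proper module just above the cut
    absorb_limit = cut + 0.75 * (h_max - cut)
    node_members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, (a, b, height, _) in enumerate(dend.merge):
        a, b = int(a), int(b)
        node_members[n + step] = node_members[a] + node_members[b]
        if height <= cut or height > absorb_limit:
            continue
        for side, other in ((a, b), (b, a)):
            side_labels = set(labels[node_members[side]].tolist())
            if len(side_labels) != 1:
                continue
            lab = side_labels.pop()
            if sizes.get(lab, 0) >= min_module_size:
                continue
            proper = {
                l for l in set(labels[node_members[other]].tolist())
                if sizes.get(l, 0) >= min_module_size
            }
            if len(proper) == 1:
                target = proper.pop()
                labels[node_members[side]] = target
                sizes[target] += sizes.pop(lab)

    out = np.zeros(n, dtype=int)
    order: list[tuple[int, str, int]] = []  # (-size, first gene id, raw label)
    for lab, size in sizes.items():
        if size >= min_module_size:
            members = np.flatnonzero(labels == lab)
            order.append((-size, min(dend.gene_ids[i] for i in members), lab))
    for new, (_, _, old) in enumerate(sorted(order), start=1):
        out[labels == old] = new
    return ModuleAssignment(dend.gene_ids, out, variant=variant)


def regulator_group(
    assign: ModuleAssignment,
    regulator_gene: str,
    filtered_ids=(),
) -> tuple[int, list[str]]:
    """Module label and co-members of the module containing a regulator.

    ``filtered_ids`` lets callers pass the ids removed upstream so the
    error message can distinguish a filtered-out regulator from an unknown
    one.
    """
    if regulator_gene not in assign.gene_ids:
        if regulator_gene in set(filtered_ids):
            raise KeyError(
                f"regulator {regulator_gene!r} was removed by expression filtering"
            )
        raise KeyError(f"unknown regulator gene id {regulator_gene!r}")
    label = assign.label_of(regulator_gene)
    if label == 0:
        warnings.warn(
            f"regulator {regulator_gene!r} is unassigned (module 0)", stacklevel=2
        )
    return label, assign.members(label)
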