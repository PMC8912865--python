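"""Synthetic TPM matrices with planted coexpression modules.

The generator emulates the shape of a fungal carbon-source transcriptome
experiment: a handful of conditions (cellulose vs glucose by default) with
biological replicates, a few hundred to a few thousand transcripts, and a
known ("planted") module structure. Each planted module m has a latent
per-sample eigenprofile e_m; a member gene g is

    x_g = loading_g * e_m + Normal(0, noise_sd)   per sample,

then shifted to minimum 0 and rescaled to a target mean so values look
like TPM (positive affine maps leave Pearson correlations untouched, so
the planted truth survives the rescaling exactly). Background genes are
i.i.d. noise. Designated regulator transcripts (e.g. xyr1, cre1) are
planted as ordinary members of an assigned module so the downstream
regulator-group, first-neighbor and shortest-path machinery has ground
truth to recover.

A condition offset can be added to eigenprofiles (alternating sign per
module) so synthetic differential expression between the two carbon
sources exists and DE-status tallies are testable.

Not modelled: read counts, library-size effects, RNA-Seq error models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import AnnotationTable
from .io import ExpressionMatrix, write_expression

__all__ = ["SyntheticDesign", "SyntheticTruth", "generate_expression",
           "generate_annotations", "scale_free_probe_correlation",
           "write_dataset"]

_CAZYME_POOL = ("GH18", "GH5", "GH6", "GH3", "GH1", "GT90", "GT2",
                "CE5", "PL7", "AA9", "CBM1")
_TF_POOL = ("Zn2Cys6", "C2H2", "fungal_specific", "SteA")
_TRANSPORTER_POOL = ("MFS", "ABC", "amino_acid", "ion")
_KO_POOL = ("carbohydrate metabolism", "energy metabolism",
            "amino acid metabolism", "lipid metabolism",
            "metabolism of cofactors and vitamins")


@dataclass
class SyntheticDesign:
    """Parameters of one synthetic dataset.

    Defaults give the desk-scale design: 5 modules x 100 genes plus 100
    background genes over 20 samples (2 conditions x 10 replicates),
    within-module noise_sd 0.3 against unit-variance eigenprofiles.
    """

    n_modules: int = 5
    genes_per_module: int = 100
    module_sizes: tuple | None = None  # per-module override of genes_per_module
    n_background_genes: int = 100
    conditions: tuple = (("cellulose", 10), ("glucose", 10))
    noise_sd: float = 0.3
    loading_range: tuple = (0.5, 1.0)
    regulator_assignments: dict = field(default_factory=dict)
    condition_effect: float = 0.0
    target_mean_tpm: float = 50.0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(int(r) for _, r in self.conditions)

    def validate(self) -> None:
        for name in ("n_modules", "genes_per_module"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count, got {getattr(self, name)}")
        if self.module_sizes is not None:
            if len(self.module_sizes) != self.n_modules:
                raise ValueError(
                    f"module_sizes has {len(self.module_sizes)} entries "
                    f"for n_modules={self.n_modules}"
                )
            if any(s < 1 for s in self.module_sizes):
                raise ValueError(f"module_sizes must be positive counts, got {self.module_sizes}")
        if self.n_background_genes < 0:
            raise ValueError(f"n_background_genes must be >= 0, got {self.n_background_genes}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"loading_range must lie in (0, 1], got {self.loading_range}")
        if self.n_samples < 2:
            raise ValueError(f"need >= 2 samples, got {self.n_samples}")
        for reg, mod in self.regulator_assignments.items():
            if not 1 <= int(mod) <= self.n_modules:
                raise ValueError(
                    f"regulator {reg!r} assigned to module {mod}, "
                    f"valid modules are 1..{self.n_modules}"
                )


@dataclass
class SyntheticTruth:
    """Planted ground truth: gene -> module map and the latent profiles."""

    module_of_gene: dict[str, int]  # 0 = background
    eigenprofiles: np.ndarray  # (n_modules, n_samples)
    condition_effects: np.ndarray  # per-module signed offset amplitude

    def labels_for(self, gene_ids) -> np.ndarray:
        return np.array([self.module_of_gene[g] for g in gene_ids], dtype=int)

    def module_members(self, module: int) -> list[str]:
        return [g for g, m in self.module_of_gene.items() if m == module]


def generate_expression(design: SyntheticDesign) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a TPM matrix with planted modules. Deterministic given seed."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    n_s = design.n_samples

    sample_ids, cond_labels = [], []
    for cond, reps in design.conditions:
        for r in range(1, int(reps) + 1):
            sample_ids.append(f"{cond}_{r}")
            cond_labels.append(cond)
    first_cond = design.conditions[0][0]
    cond_mask = np.array([c == first_cond for c in cond_labels], dtype=float)

    eigen = rng.standard_normal((design.n_modules, n_s))
    effects = np.zeros(design.n_modules)
    if design.condition_effect > 0:
        # alternate sign so both up- and downregulated modules are planted
        effects = design.condition_effect * np.array(
            [1 if m % 2 == 0 else -1 for m in range(design.n_modules)], dtype=float
        )
        eigen = eigen + effects[:, None] * cond_mask[None, :]

    regulators_by_module: dict[int, list[str]] = {}
    for reg in sorted(design.regulator_assignments):
        regulators_by_module.setdefault(
            int(design.regulator_assignments[reg]), []
        ).append(reg)

    gene_ids: list[str] = []
    module_of: dict[str, int] = {}
    rows: list[np.ndarray] = []
    sizes = (design.module_sizes if design.module_sizes is not None
             else [design.genes_per_module] * design.n_modules)
    for m in range(1, design.n_modules + 1):
        names = [f"m{m:02d}_g{i:03d}" for i in range(1, sizes[m - 1] + 1)]
        names += regulators_by_module.get(m, [])
        for name in names:
            loading = rng.uniform(*design.loading_range)
            x = loading * eigen[m - 1] + rng.normal(0.0, design.noise_sd, n_s)
            rows.append(x)
            gene_ids.append(name)
            module_of[name] = m
    for i in range(1, design.n_background_genes + 1):
        name = f"bg_g{i:03d}"
        rows.append(rng.standard_normal(n_s))
        gene_ids.append(name)
        module_of[name] = 0

    mat = np.vstack(rows)
    mat = mat - mat.min(axis=1, keepdims=True)  # TPM-like: non-negative
    means = mat.mean(axis=1, keepdims=True)
    scale = np.where(means > 0, design.target_mean_tpm / np.where(means > 0, means, 1.0), 1.0)
    mat = mat * scale

    values = pd.DataFrame(mat, index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "condition": cond_labels,
            "replicate": [int(s.rsplit("_", 1)[1]) for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    truth = SyntheticTruth(module_of, eigen, effects)
    return ExpressionMatrix(values, meta), truth


def scale_free_probe_correlation(n_genes: int = 300, attach: int = 2,
                                 r_range: tuple = (0.7, 1.0), seed: int = 0):
    """Correlation matrix with a planted scale-free (power-law) topology.

    Wires genes by preferential attachment (each new gene attaches to
    ``attach`` existing genes), then draws a strong positive correlation
    from ``r_range`` for every wired pair and zero elsewhere. At high
    soft powers the signed adjacency approaches the wiring indicator, so
    the degree distribution is power-law-like and the soft-power scan
    should find a power whose scale-free fit is high. Intended as a
    verification probe for pick_soft_power, not as expression data.
    """
    import networkx as nx

    from .network import CorrelationMatrix

    rng = np.random.default_rng(seed)
    graph = nx.barabasi_albert_graph(n_genes, attach, seed=int(seed) % (2**31))
    r = np.zeros((n_genes, n_genes))
    for u, v in graph.edges():
        r[u, v] = r[v, u] = rng.uniform(*r_range)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix([f"g{i:04d}" for i in range(n_genes)], r)


def generate_annotations(
    truth: SyntheticTruth,
    terms_per_module: int = 5,
    enrichment_fraction: float = 0.8,
    background_rate: float = 0.02,
    category_fraction: float = 0.1,
    seed: int = 0,
) -> AnnotationTable:
    """GO-like and functional-category fixture annotations for planted truth.

    Each planted module m gets ``terms_per_module`` dedicated terms
    ``GO:M<m>T<t>``, annotated to ``enrichment_fraction`` of its genes;
    every other gene carries each term with probability
    ``background_rate``. CAZyme-family / TF-class / transporter-class /
    KO-class labels are sprinkled over random ``category_fraction``
    subsets, and DE status follows the planted condition effects (all
    genes of a module with a positive cellulose offset are 'up', negative
    'down').
    """
    if not truth.module_of_gene:
        raise ValueError("truth is empty: no genes to annotate")
    if not 0 < enrichment_fraction <= 1:
        raise ValueError(
            f"enrichment_fraction must be in (0, 1], got {enrichment_fraction}"
        )
    if terms_per_module < 0:
        raise ValueError(f"terms_per_module must be >= 0, got {terms_per_module}")
    rng = np.random.default_rng(seed)
    genes = list(truth.module_of_gene)
    n_modules = truth.eigenprofiles.shape[0]

    go: dict[str, set[str]] = {}
    for m in range(1, n_modules + 1):
        members = truth.module_members(m)
        n_annot = int(round(enrichment_fraction * len(members)))
        for t in range(1, terms_per_module + 1):
            term = f"GO:M{m}T{t}"
            chosen = rng.choice(members, size=n_annot, replace=False) if n_annot else []
            for g in chosen:
                go.setdefault(str(g), set()).add(term)
            if background_rate > 0:
                outside = [g for g in genes if truth.module_of_gene[g] != m]
                hits = rng.random(len(outside)) < background_rate
                for g, h in zip(outside, hits):
                    if h:
                        go.setdefault(g, set()).add(term)

    def sprinkle(pool):
        n = max(1, int(round(category_fraction * len(genes))))
        chosen = rng.choice(genes, size=n, replace=False)
        return {str(g): str(rng.choice(pool)) for g in sorted(chosen)}

    de_status = {}
    for g, m in truth.module_of_gene.items():
        if m == 0 or truth.condition_effects[m - 1] == 0:
            de_status[g] = "none"
        else:
            de_status[g] = "up" if truth.condition_effects[m - 1] > 0 else "down"

    return AnnotationTable(
        go=go,
        cazyme_family=sprinkle(_CAZYME_POOL),
        tf_class=sprinkle(_TF_POOL),
        transporter_class=sprinkle(_TRANSPORTER_POOL),
        ko_pathway_class=sprinkle(_KO_POOL),
        de_status=de_status,
    )


def write_dataset(
    directory,
    design: SyntheticDesign,
    annotations_seed: int | None = None,
    **annotation_kwargs,
) -> dict[str, Path]:
    """Generate and write a full synthetic dataset as TSV files.

    Emits expression.tsv, samples.tsv, truth.tsv and the annotation TSVs,
    all in the dialects the readers in this package consume.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_expression(design)
    paths = {
        "expression": directory / "expression.tsv",
        "samples": directory / "samples.tsv",
        "truth": directory / "truth.tsv",
    }
    write_expression(matrix, paths["expression"], paths["samples"])
    pd.DataFrame(
        sorted(truth.module_of_gene.items()), columns=["gene", "module"]
    ).to_csv(paths["truth"], sep="\t", index=False)
    ann = generate_annotations(
        truth,
        seed=design.seed if annotations_seed is None else annotations_seed,
        **annotation_kwargs,
    )
    paths.update(ann.write_tsvs(directory))
    return paths
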