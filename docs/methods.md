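# Methods

## Model and pipeline

The package treats a transcriptome as a genes × samples matrix of TPM
values with per-sample condition labels (e.g. carbon source) and
replicate indices. The analysis is correlation-based throughout and
assumes that coexpression — similarity of expression profiles across
samples — is informative about shared regulation. Nine stages run in a
fixed order: low-expression filter → Pearson correlation → soft-power
selection → signed adjacency → topological overlap (TOM) → hierarchical
clustering and adaptive tree cut → regulator-group lookup → HRR network
and topology → enrichment.

**Filtering.** A transcript is removed when its fraction of zero-TPM
samples exceeds `max_zero_fraction` (default 0.5) in *every* condition.
The per-condition rule deliberately keeps condition-specific
transcripts: a gene silent on glucose but expressed in all cellulose
replicates survives. A pooled variant is available
(`per_condition=False`). "Zero" means exactly 0.0; TPM tables carry no
missing-value sentinel. Constant genes are dropped separately because
Pearson correlation is undefined at zero variance. Networks are built
on raw TPM by default; `log2(TPM+1)` is available behind a flag since
correlation-based module structure is usually similar but not identical
under the transform.

**Signed adjacency and soft power.** The signed transform
a = ((1+r)/2)^β maps r = −1 to 0 and r = +1 to 1, so anticorrelated
pairs are *not* connected. β (integer grid 1–50 by default) is chosen
as the smallest power whose scale-free fit index reaches `r2_target`
(default 0.8). The fit index bins node connectivities k into 10
equal-width bins, regresses log₁₀(bin frequency) on log₁₀(mean bin k)
over non-empty bins, and signs R² by the negated slope, so only
decreasing degree distributions score positively. Degenerate inputs
(all k equal, fewer than two usable bins, zero x-variance) return a
flagged fit of 0 rather than an error. When no candidate reaches the
target, the pipeline logs a warning and falls back to the best-fitting
power; the scan table is always written so the choice is auditable.

**TOM and clustering.** TOM uses the standard unsigned overlap formula
on the signed adjacency, computed as a matrix product with the diagonal
excluded from connectivity; entries are clipped to [0, 1] and the
matrix symmetrized to absorb floating-point drift (a brute-force
triple-loop equivalence within 1e−10 is enforced in tests). Average
linkage on 1 − TOM (scipy) gives the dendrogram; scipy's deterministic
merge order plus (value, gene id) tie-breaking makes repeated runs
byte-identical.

**Adaptive tree cut.** The module detector is a deliberately simple
top-down variant of adaptive dendrogram cutting, recorded in output
metadata as `tree-cut(q, ds)`: cut the tree at `q × max merge height`
(q = `cut_height_quantile`, default 0.99, shifted by ±0.0025 per
`deep_split` step away from its default of 2 so that deeper splitting
lowers the cut); branches below the cut with ≥ `min_module_size`
(default 30) leaves are proper modules. A smaller branch is merged
upward into a proper module when the dendrogram joins it to exactly one
such module within 75% of the remaining height range above the cut —
this recovers peripheral module members that attach just above the cut
— otherwise it is labelled 0 (unassigned). Labels are renumbered by
descending size. There is no PAM-like reassignment stage; correctness
is asserted as planted-module recovery (adjusted Rand index ≥ 0.8 at
the default synthetic design), not label-for-label agreement with any
particular reference implementation.

**HRR network.** Every gene ranks all partners by descending r (ties by
gene id); edge (i, j) requires r ≥ `r_threshold` (default 0.8) and
max(rankᵢ(j), rankⱼ(i)) ≤ `max_rank` (default 30). The threshold
applies to positive r only, matching the signed-network reading of
"coexpressed"; an `absolute` flag admits |r| and is logged prominently
when used, because anticorrelated edges change the meaning of
neighborhoods. Band weights 1/5, 1/15, 1/30 code the rank intervals
[1,10], [11,20], [21,30] — the only reading that gives three disjoint
codes — and are carried as edge attributes for export/visualization
only; all path analyses treat the graph as unweighted, since the
quantity of interest is the minimal number of edges.

**Topology.** Hubs are the nodes tied at the `top_k` highest distinct
degree values, computed within the regulator's module subnetwork by
default (a global flag exists) because per-group hubs are the objects
of interest. Geodesic distance and the number of distinct shortest
paths come from one BFS per source with the predecessor-sum recurrence
count(v) = Σ count(u) over predecessors at distance d(v)−1; exhaustive
path enumeration exists only as a test oracle. For distance-2 pairs the
middle nodes ("transitive transcripts") are reported — candidate relays
between a regulator and a target. Unreachable or absent targets are
reported explicitly with a reason, never with sentinel numbers. The
regulator × CAZyme report emits two matrices in long format: geodesic
length and geodesic count per pair.

**Enrichment.** Classic one-sided Fisher's exact test per GO term:
p = P(X ≥ k) for a hypergeometric draw (N background genes, K
annotated, module of n, overlap k), computed via `scipy.stats.hypergeom.sf`.
No ontology-graph propagation or elim/weight decorrelation is applied;
annotations are taken as supplied flat mappings, and the default
criterion is raw p < α (α = 0.05) with Benjamini–Hochberg available
behind a flag. The background defaults to all filtered transcripts and
is configurable. Category tallies count module genes per CAZyme family
(with a class view aggregating by alphabetic prefix: GH18 → GH), TF
class, transporter class, KO pathway class, or DE status.

## Synthetic data: what it does and does not emulate

`generate_expression` plants M modules: module m has a latent
eigenprofile e_m ~ N(0, I) over samples; member gene g is
loading_g · e_m + N(0, noise_sd²) per sample, with loadings uniform in
(0.5, 1.0]. Each gene is then shifted to min 0 and rescaled to a target
mean (default 50), giving TPM-like non-negative values; positive affine
maps preserve Pearson correlation exactly, so the planted truth
survives. Background genes are i.i.d. unit-normal noise. Regulators are
planted as ordinary members of an assigned module. An optional
condition offset (alternating sign per module) plants differential
expression between the two conditions so DE tallies are testable.
Defaults — 5 modules × 100 genes, 100 background genes, 2 conditions ×
10 replicates, noise_sd 0.3 — are the desk-scale stand-in for a
filtered fungal transcriptome (~11k transcripts, 3 replicates × 2
carbon sources); the 6-sample design is supported, but recovery
assertions are made only at ≥ 20 samples because 6-sample correlations
are too noisy for honest guarantees. `module_sizes` can override the
uniform size, and `scale_free_probe_correlation` wires a
preferential-attachment topology (300 genes, 2 attachments, edge r in
[0.7, 1]) as a verification probe for the soft-power scan — equal-size
planted modules give near-homogeneous connectivity and are *not* a
scale-free benchmark.

Not modelled: read counts and their overdispersion, library-size and
batch effects, correlated background structure, annotation bias. A
passing suite therefore shows the algorithms are correct on data
matching their assumptions, not that module recovery at these rates
transfers to any real transcriptome.

`generate_annotations` gives each module `terms_per_module` dedicated
GO-like terms annotated to `enrichment_fraction` (default 0.8) of its
genes plus a `background_rate` (default 0.02) elsewhere, and sprinkles
CAZyme/TF/transporter/KO labels over random subsets; DE status follows
the planted condition effects.

## Numerical choices and degenerate inputs

- Correlations are clipped to [−1, 1] and symmetrized; diagonals are
  set exactly to 1. Adjacency and TOM are bound-checked on
  construction.
- All ties (neighbor ranks, hub ordering, module renumbering,
  enrichment output) break by lexicographic gene id after the primary
  value, so every artifact is deterministic.
- Singleton inputs produce trivial dendrograms; `min_module_size`
  exceeding the gene count yields an all-unassigned labelling with a
  warning rather than an error.
- A regulator missing from the assignment raises an error that
  distinguishes "removed by filtering" from "unknown id".
- Every source of randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); the pipeline manifest contains no
  timestamps, so identical configs and seeds give byte-identical
  manifests, which is asserted as the determinism contract.

## Problem sizes used in tests and the acceptance script

Planted-module recovery runs at 600 genes × 20 samples; TOM and HRR
oracle equivalence at 20 and ≤ 10 genes over 100 randomized trials;
geodesic-count equivalence on 100 random graphs of ≤ 8 nodes; Fisher
equivalence on 1,000 random configurations with N ≤ 200; the zero-noise
sanity stack at 3 modules × 10 genes over 30 samples with β = 30 and
`min_module_size` 5 (a module must have ≤ 11 members for full top-band
connectivity, since a gene has at most 10 rank-≤10 partners). These
sizes keep every check comfortably reproducible on a single CPU while
exercising the same code paths as full-scale runs.

## Known limitations

- The tree-cut variant is simpler than hybrid dynamic cutting with PAM;
  on weakly separated modules it assigns fewer genes (label 0) rather
  than forcing membership.
- The scale-free fit depends on the 10-bin histogram; very small or
  spiky networks (near-clique modules with little noise) can fit poorly
  at every β, in which case the fallback power and the warning in the
  scan output should be inspected.
- Module eigengenes, module–trait correlation, weighted shortest paths
  and centralities beyond degree are out of scope.
- GO enrichment ignores the ontology graph; a term and its ancestors
  are treated as unrelated annotations.
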