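"""GO-term overrepresentation in a regulator's module.

Fisher's exact test (one-sided hypergeometric upper tail) against the
background of all filtered transcripts; terms with p < 0.05 are flagged
as enriched.
"""

import coexnet as cx

design = cx.SyntheticDesign(
    n_modules=2, genes_per_module=40, n_background_genes=40,
    noise_sd=0.2, condition_effect=1.5, seed=3,
    regulator_assignments={"cre1": 1},
)
matrix, truth = cx.generate_expression(design)
ann = cx.generate_annotations(truth, terms_per_module=3,
                              enrichment_fraction=0.8, seed=3)

corr = cx.pearson_matrix(matrix)
tom = cx.topological_overlap(cx.signed_adjacency(corr, 12))
assign = cx.dynamic_tree_cut(cx.cluster_dendrogram(tom), min_module_size=20)
label, members = cx.regulator_group(assign, "cre1")

result = cx.go_enrichment(members, matrix.gene_ids, ann, alpha=0.05)
print(result.head(6).to_string(index=False))
print(f"{int(result['enriched'].sum())} enriched terms in the cre1 group")

up, down, total = cx.de_overlap(members, ann)
print(f"differential expression in the group: {up} up, {down} down of {total}")
# Terms dedicated to the planted module 1 (GO:M1T*) should top the list
# with tiny p-values; background terms should sit near p = 1.
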