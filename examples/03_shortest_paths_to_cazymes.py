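"""Shortest paths from regulators to CAZyme transcripts.

For each (regulator, CAZyme) pair the geodesic distance (minimal number
of edges) and the number of distinct shortest paths are computed on the
HRR graph; for distance-2 pairs the transitive (middle) transcripts are
candidate relays between the regulator and the enzyme.
"""

import coexnet as cx

design = cx.SyntheticDesign(
    n_modules=2, genes_per_module=40, n_background_genes=10,
    noise_sd=0.4, seed=8, regulator_assignments={"xyr1": 1, "cre1": 2},
)
matrix, truth = cx.generate_expression(design)
ann = cx.generate_annotations(truth, seed=8, category_fraction=0.3)
corr = cx.pearson_matrix(matrix)
net = cx.build_hrr_network(corr, r_threshold=0.7)

cazymes = sorted(g for g in ann.cazyme_family if g in net)[:6]
table = cx.regulator_cazyme_matrix(net, ["xyr1", "cre1"], cazymes)
print(table.to_string(index=False))

for _, row in table.iterrows():
    if row["distance"] == 2:
        middles, _ = cx.transitive_transcripts(net, row["regulator"], row["cazyme"])
        print(f"transitive transcripts {row['regulator']} -> {row['cazyme']}: "
              f"{middles[:4]}{' ...' if len(middles) > 4 else ''}")
# distance 1 = the enzyme is a first neighbor of the regulator;
# n_geodesics counts the distinct minimal routes (larger = more parallel
# coexpression paths linking the regulator to that enzyme).
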