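"""Fisher/hypergeometric GO enrichment and functional-category tallies."""

from fractions import Fraction
from math import comb

import pytest

import coexnet as cx


def exact_tail(N, K, n, k):
    """Exact hypergeometric upper tail P(X >= k) via rational arithmetic."""
    total = Fraction(0)
    for x in range(k, min(n, K) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(total)


def annotations_for(term_to_genes):
    go = {}
    for term, genes in term_to_genes.items():
        for g in genes:
            go.setdefault(g, set()).add(term)
    return cx.AnnotationTable(go=go)


class TestGoEnrichment:
    def test_fully_contained_annotation_is_point_mass(self):
        background = [f"g{i}" for i in range(100)]
        module = background[:10]
        ann = annotations_for({"GO:X": module})
        res = cx.go_enrichment(module, background, ann)
        row = res.iloc[0]
        # k = K = n = 10: p = 1 / C(100, 10)
        assert row["p_value"] == pytest.approx(1 / comb(100, 10), rel=1e-12)
        assert row["enriched"]

    def test_ubiquitous_term_not_enriched(self):
        background = [f"g{i}" for i in range(50)]
        ann = annotations_for({"GO:ALL": background})
        res = cx.go_enrichment(background[:5], background, ann)
        assert res.iloc[0]["p_value"] == pytest.approx(1.0)
        assert not res.iloc[0]["enriched"]

    def test_known_configuration_equals_exact_sum(self):
        background = [f"g{i}" for i in range(100)]
        module = background[:10]
        annotated = module[:5] + background[50:55]  # k=5 of K=10
        ann = annotations_for({"GO:T": annotated})
        res = cx.go_enrichment(module, background, ann)
        assert res.iloc[0]["p_value"] == pytest.approx(
            exact_tail(100, 10, 10, 5), abs=1e-12
        )

    def test_random_configurations_match_exact_tail(self):
        import numpy as np

        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(10, 201))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            background = [f"g{i}" for i in range(N)]
            annotated = list(rng.choice(background, K, replace=False))
            module = list(rng.choice(background, n, replace=False))
            k = len(set(annotated) & set(module))
            if k == 0:
                continue
            ann = annotations_for({"GO:T": annotated})
            res = cx.go_enrichment(module, background, ann)
            assert res.iloc[0]["k"] == k
            assert res.iloc[0]["p_value"] == pytest.approx(
                exact_tail(N, K, n, k), abs=1e-12
            )

    def test_p_nonincreasing_in_overlap(self):
        N, K, n = 100, 10, 10
        ps = [exact_tail(N, K, n, k) for k in range(1, 11)]
        background = [f"g{i}" for i in range(N)]
        for k in range(1, 11):
            module = background[:n]
            annotated = module[:k] + background[n:n + K - k]
            ann = annotations_for({"GO:T": annotated})
            res = cx.go_enrichment(module, background, ann)
            assert res.iloc[0]["p_value"] == pytest.approx(ps[k - 1], abs=1e-12)
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_results_sorted_by_p_then_term(self):
        background = [f"g{i}" for i in range(40)]
        module = background[:8]
        ann = annotations_for({
            "GO:B": module[:6], "GO:A": module[:2] + background[20:30],
            "GO:C": module[:6],
        })
        res = cx.go_enrichment(module, background, ann)
        assert list(res["term"][:2]) == ["GO:B", "GO:C"]  # tie broken by id

    def test_empty_module_warns_and_returns_empty(self):
        ann = annotations_for({"GO:T": ["g1"]})
        with pytest.warns(UserWarning, match="empty"):
            res = cx.go_enrichment([], ["g1", "g2"], ann)
        assert len(res) == 0

    def test_module_outside_background_rejected(self):
        ann = annotations_for({})
        with pytest.raises(ValueError, match="not in background"):
            cx.go_enrichment(["x"], ["g1", "g2"], ann)

    def test_bh_correction_flag(self):
        background = [f"g{i}" for i in range(60)]
        module = background[:10]
        ann = annotations_for({f"GO:{i}": module[:3] + background[20 + i:40 + i]
                               for i in range(5)})
        res = cx.go_enrichment(module, background, ann, bh_correction=True)
        assert "p_adjusted" in res.columns
        assert (res["p_adjusted"] >= res["p_value"] - 1e-15).all()


class TestCategoryTally:
    def test_family_and_class_views(self):
        ann = cx.AnnotationTable(
            cazyme_family={"g1": "GH18", "g2": "GH18", "g3": "GT90"}
        )
        fam = cx.category_tally(["g1", "g2", "g3", "g4"], ann, "cazyme_family")
        assert fam == {"GH18": 2, "GT90": 1}
        cls = cx.category_tally(["g1", "g2", "g3", "g4"], ann, "cazyme_class")
        assert cls == {"GH": 2, "GT": 1}

    def test_cbm_prefix_aggregation(self):
        ann = cx.AnnotationTable(cazyme_family={"g1": "CBM1", "g2": "AA9"})
        assert cx.category_tally(["g1", "g2"], ann, "cazyme_class") == \
            {"AA": 1, "CBM": 1}

    def test_no_annotated_genes_gives_empty_tally(self):
        ann = cx.AnnotationTable(tf_class={"other": "C2H2"})
        assert cx.category_tally(["g1"], ann, "tf_class") == {}

    def test_unknown_category_rejected_listing_valid_names(self):
        ann = cx.AnnotationTable()
        with pytest.raises(ValueError, match="cazyme_family"):
            cx.category_tally(["g1"], ann, "nope")

    def test_tally_conserves_annotated_gene_count(self):
        design = cx.SyntheticDesign(n_modules=2, genes_per_module=20,
                                    n_background_genes=10, seed=1)
        _, truth = cx.generate_expression(design)
        ann = cx.generate_annotations(truth, seed=1)
        genes = list(truth.module_of_gene)
        tally = cx.category_tally(genes, ann, "cazyme_family")
        assert sum(tally.values()) == len(ann.cazyme_family)

    def test_planted_counts_recovered(self):
        ann = cx.AnnotationTable(
            cazyme_family={f"g{i}": "GH5" for i in range(7)}
            | {f"g{i}": "AA9" for i in range(7, 10)}
        )
        tally = cx.category_tally([f"g{i}" for i in range(10)], ann,
                                  "cazyme_family")
        assert tally == {"AA9": 3, "GH5": 7}


class TestDeOverlap:
    def test_all_none(self):
        ann = cx.AnnotationTable(de_status={"g1": "none", "g2": "none"})
        assert cx.de_overlap(["g1", "g2"], ann) == (0, 0, 2)

    def test_planted_up_fraction(self):
        ann = cx.AnnotationTable(
            de_status={f"g{i}": ("up" if i < 7 else "none") for i in range(20)}
        )
        up, down, total = cx.de_overlap([f"g{i}" for i in range(20)], ann)
        assert (up, down, total) == (7, 0, 20)

    def test_disjoint_module_warns_with_zero_counts(self):
        ann = cx.AnnotationTable(de_status={"other": "up"})
        with pytest.warns(UserWarning, match="overlap"):
            up, down, total = cx.de_overlap(["g1", "g2"], ann)
        assert (up, down) == (0, 0)

    def test_invalid_status_rejected(self):
        with pytest.raises(ValueError, match="de_status"):
            cx.AnnotationTable(de_status={"g1": "sideways"})
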