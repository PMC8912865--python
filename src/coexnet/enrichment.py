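"""GO overrepresentation and functional-category tallies for modules.

Enrichment is the classic one-sided Fisher's exact test: for a term
annotated to K of N background genes and k of n module genes, the p-value
is the hypergeometric upper tail P(X >= k). No ontology-graph propagation
is applied — annotations are taken exactly as supplied. An optional
Benjamini-Hochberg correction is available but off by default; the raw
p < alpha rule (alpha = 0.05) is the primary criterion.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "AnnotationTable",
    "go_enrichment",
    "category_tally",
    "de_overlap",
    "CATEGORY_NAMES",
]

CATEGORY_NAMES = (
    "cazyme_family",
    "cazyme_class",
    "tf_class",
    "transporter_class",
    "ko_pathway_class",
    "de_status",
)

_FAMILY_PREFIX = re.compile(r"^([A-Za-z]+)")


@dataclass
class AnnotationTable:
    """Flat gene -> annotation mappings.

    ``go`` maps each gene id to its set of GO terms; the category dicts
    are optional single-valued labels (CAZyme family such as GH18, TF
    class such as Zn2Cys6, transporter class such as MFS, KO pathway
    class); ``de_status`` maps genes to 'up', 'down' or 'none'.
    """

    go: dict[str, set[str]] = field(default_factory=dict)
    cazyme_family: dict[str, str] = field(default_factory=dict)
    tf_class: dict[str, str] = field(default_factory=dict)
    transporter_class: dict[str, str] = field(default_factory=dict)
    ko_pathway_class: dict[str, str] = field(default_factory=dict)
    de_status: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("cazyme_family", "tf_class", "transporter_class",
                     "ko_pathway_class"):
            mapping = getattr(self, name)
            empty = [g for g, v in mapping.items() if not str(v).strip()]
            if empty:
                raise ValueError(f"empty {name} label for gene(s) {empty[:5]}")
        bad = {v for v in self.de_status.values()} - {"up", "down", "none"}
        if bad:
            raise ValueError(f"de_status values must be up/down/none, got {sorted(bad)}")

    def category_of(self, gene: str) -> str | None:
        """Best single functional label: CAZyme > TF > transporter > KO class."""
        for mapping, tag in (
            (self.cazyme_family, "CAZyme"),
            (self.tf_class, "TF"),
            (self.transporter_class, "transporter"),
            (self.ko_pathway_class, "KO"),
        ):
            if gene in mapping:
                return f"{tag}:{mapping[gene]}"
        return None

    # -- TSV round trip (two-column gene<TAB>term, one row per assignment) --

    def write_tsvs(self, directory) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        go_rows = [
            {"gene": g, "term": t}
            for g in sorted(self.go)
            for t in sorted(self.go[g])
        ]
        paths["go"] = directory / "go_terms.tsv"
        pd.DataFrame(go_rows, columns=["gene", "term"]).to_csv(
            paths["go"], sep="\t", index=False
        )
        for name in ("cazyme_family", "tf_class", "transporter_class",
                     "ko_pathway_class", "de_status"):
            mapping = getattr(self, name)
            paths[name] = directory / f"{name}.tsv"
            pd.DataFrame(
                sorted(mapping.items()), columns=["gene", "term"]
            ).to_csv(paths[name], sep="\t", index=False)
        return paths

    @classmethod
    def from_tsvs(
        cls,
        go_path=None,
        cazyme_path=None,
        tf_path=None,
        transporter_path=None,
        ko_path=None,
        de_path=None,
    ) -> "AnnotationTable":
        def read_pairs(path):
            df = pd.read_csv(path, sep="\t", dtype=str)
            if list(df.columns[:2]) != ["gene", "term"]:
                raise ValueError(
                    f"{path}: expected columns gene, term; got {list(df.columns)}"
                )
            return df

        go: dict[str, set[str]] = {}
        if go_path is not None:
            for _, row in read_pairs(go_path).iterrows():
                go.setdefault(row["gene"], set()).add(row["term"])

        def read_map(path):
            if path is None:
                return {}
            return dict(read_pairs(path).values.tolist())

        return cls(
            go=go,
            cazyme_family=read_map(cazyme_path),
            tf_class=read_map(tf_path),
            transporter_class=read_map(transporter_path),
            ko_pathway_class=read_map(ko_path),
            de_status=read_map(de_path),
        )


def go_enrichment(
    module_genes,
    background_genes,
    annotations: AnnotationTable,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """One-sided Fisher overrepresentation of GO terms in a module.

    For every term annotated to at least one module gene, computes the
    hypergeometric upper tail P(X >= k) with population N = background
    size, K = background genes carrying the term, draw n = module size.
    Results are sorted by ascending p, ties by term id. ``enriched`` is
    p < alpha (on BH-adjusted p when ``bh_correction`` is on).
    """
    module = list(dict.fromkeys(module_genes))
    background = list(dict.fromkeys(background_genes))
    if len(background) < 2:
        raise ValueError("background must contain at least 2 genes")
    extra = set(module) - set(background)
    if extra:
        raise ValueError(f"module genes not in background: {sorted(extra)[:5]}")
    cols = ["term", "k", "n", "K", "N", "p_value", "enriched"]
    if not module:
        warnings.warn("empty module: no enrichment computed", stacklevel=2)
        return pd.DataFrame(columns=cols)
    N, n = len(background), len(module)
    bg_counts: Counter = Counter()
    mod_counts: Counter = Counter()
    module_set = set(module)
    for g in background:
        for t in annotations.go.get(g, ()):
            bg_counts[t] += 1
            if g in module_set:
                mod_counts[t] += 1
    rows = []
    for term in sorted(mod_counts):
        k, K = mod_counts[term], bg_counts[term]
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, 0.0), 1.0)
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "p_value": p})
    df = pd.DataFrame(rows, columns=cols[:-1])
    if df.empty:
        df["enriched"] = pd.Series(dtype=bool)
        return df
    df = df.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["enriched"] = df["p_adjusted"] < alpha
    else:
        df["enriched"] = df["p_value"] < alpha
    return df


def category_tally(
    module_genes, annotations: AnnotationTable, category: str
) -> dict[str, int]:
    """Count module genes per category value.

    ``cazyme_class`` aggregates CAZyme families into their class by
    alphabetic prefix (GH18 -> GH, CBM1 -> CBM, ...).
    """
    if category not in CATEGORY_NAMES:
        raise ValueError(
            f"unknown category {category!r}; valid: {', '.join(CATEGORY_NAMES)}"
        )
    if category == "cazyme_class":
        mapping = {
            g: _FAMILY_PREFIX.match(fam).group(1).upper()
            for g, fam in annotations.cazyme_family.items()
        }
    elif category == "de_status":
        mapping = annotations.de_status
    else:
        mapping = getattr(annotations, category)
    counts: Counter = Counter(
        mapping[g] for g in module_genes if g in mapping
    )
    return dict(sorted(counts.items()))


def de_overlap(module_genes, annotations: AnnotationTable) -> tuple[int, int, int]:
    """(n_up, n_down, n_total) differential-expression overlap of a module."""
    module = list(module_genes)
    statuses = [annotations.de_status.get(g) for g in module]
    covered = sum(s is not None for s in statuses)
    if module and covered == 0:
        warnings.warn(
            "module has no overlap with the DE-status table", stacklevel=2
        )
    n_up = sum(s == "up" for s in statuses)
    n_down = sum(s == "down" for s in statuses)
    return n_up, n_down, len(module)
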