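"""End-to-end pipeline: filter -> correlation -> soft power -> TOM ->
modules -> regulator groups -> HRR -> topology -> enrichment.

Every run writes its stage outputs plus a ``manifest.json`` recording the
package version, all parameters, per-stage summaries and sha256 checksums
of every output file. The manifest contains no timestamps, so two runs
with the same configuration and seed produce byte-identical manifests —
that equality is the pipeline's determinism contract.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .enrichment import AnnotationTable, category_tally, de_overlap, go_enrichment
from .hrr import build_hrr_network, edge_table, module_subnetwork, write_graphml
from .io import drop_constant_genes, filter_low_expression, read_expression, write_expression
from .network import (
    cluster_dendrogram,
    dynamic_tree_cut,
    pearson_matrix,
    pick_soft_power,
    regulator_group,
    signed_adjacency,
    topological_overlap,
)
from .topology import degree_and_hubs, first_neighbors, regulator_cazyme_matrix

log = logging.getLogger("coexnet")

STAGES = (
    "filter",
    "correlation",
    "soft_power",
    "tom",
    "modules",
    "regulator_groups",
    "hrr",
    "topology",
    "enrichment",
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """All inputs and tunables of one pipeline run."""

    expression_path: str
    metadata_path: str
    out_dir: str
    go_path: str | None = None
    cazyme_path: str | None = None
    tf_path: str | None = None
    transporter_path: str | None = None
    ko_path: str | None = None
    de_path: str | None = None
    regulators: list[str] = field(default_factory=list)
    cazyme_targets: list[str] = field(default_factory=list)
    max_zero_fraction: float = 0.5
    log_transform: bool = False
    beta_candidates: list[int] = field(default_factory=lambda: list(range(1, 51)))
    r2_target: float = 0.8
    beta: int | None = None  # overrides the scan when set
    min_module_size: int = 30
    cut_height_quantile: float = 0.99
    deep_split: int = 2
    r_threshold: float = 0.8
    max_rank: int = 30
    absolute_r: bool = False
    alpha: float = 0.05
    bh_correction: bool = False
    run_enrichment: bool = True
    write_tom: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def preflight(self) -> None:
        """Validate paths and parameter ranges before any computation."""
        for name in ("expression_path", "metadata_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError("preflight", "missing_input", f"{name}: {p} does not exist")
        if self.run_enrichment and self.go_path is None:
            raise PipelineError(
                "preflight", "missing_annotation",
                "enrichment requested but no GO annotation table given "
                "(set go_path or run_enrichment=false)",
            )
        for name in ("go_path", "cazyme_path", "tf_path", "transporter_path",
                     "ko_path", "de_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError("preflight", "missing_input", f"{name}: {p} does not exist")
        if not 0 <= self.max_zero_fraction <= 1:
            raise PipelineError("preflight", "bad_parameter", "max_zero_fraction outside [0, 1]")
        if not 0 < self.r2_target <= 1.5:
            raise PipelineError("preflight", "bad_parameter", "r2_target out of range")
        if self.min_module_size < 1:
            raise PipelineError("preflight", "bad_parameter", "min_module_size must be >= 1")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.preflight()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "coexnet",
        "version": __version__,
        "parameters": asdict(config),
        "stages": [],
    }

    def record(stage: str, outputs: list[Path], **summary) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "outputs": {p.name: _sha256(p) for p in outputs},
                "summary": summary,
            }
        )
        log.info("stage %s done: %s", stage, summary)

    def guard(stage, fn, code="stage_failure"):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(stage, code, str(exc)) from exc

    # filter -------------------------------------------------------------
    def _filter():
        m = read_expression(config.expression_path, config.metadata_path)
        m, removed_zero = filter_low_expression(m, config.max_zero_fraction)
        m, removed_const = drop_constant_genes(m)
        if config.log_transform:
            m = m.log2_transform()
        return m, removed_zero + removed_const

    matrix, removed = guard("filter", _filter)
    f_expr, f_meta = out / "filtered_expression.tsv", out / "filtered_samples.tsv"
    write_expression(matrix, f_expr, f_meta)
    (out / "removed_genes.txt").write_text("\n".join(removed) + ("\n" if removed else ""))
    record("filter", [f_expr, f_meta, out / "removed_genes.txt"],
           n_genes=matrix.n_genes, n_removed=len(removed))

    # correlation ---------------------------------------------------------
    corr = guard("correlation", lambda: pearson_matrix(matrix))
    record("correlation", [], n_genes=len(corr.gene_ids))

    # soft power ----------------------------------------------------------
    def _soft_power():
        scan = pick_soft_power(corr, config.beta_candidates, config.r2_target)
        return scan

    scan = guard("soft_power", _soft_power)
    scan_path = out / "soft_power_scan.tsv"
    scan.table.to_csv(scan_path, sep="\t", index=False)
    beta = config.beta if config.beta is not None else scan.chosen_power
    if beta is None:
        beta = int(scan.table.loc[scan.table["signed_r2"].idxmax(), "power"])
        log.warning("no power reached r2 target %.2f; using best power %d",
                    config.r2_target, beta)
    record("soft_power", [scan_path], chosen_power=int(beta),
           scan_chosen=scan.chosen_power)

    # TOM ----------------------------------------------------------------
    def _tom():
        adj = signed_adjacency(corr, beta)
        return topological_overlap(adj)

    tom = guard("tom", _tom)
    tom_outputs = []
    if config.write_tom:
        if len(tom.gene_ids) > 2000:
            log.warning("TOM for %d genes is large; writing anyway", len(tom.gene_ids))
        tom_path = out / "tom.tsv"
        pd.DataFrame(tom.tom, index=tom.gene_ids, columns=tom.gene_ids).to_csv(
            tom_path, sep="\t"
        )
        tom_outputs.append(tom_path)
    record("tom", tom_outputs, n_genes=len(tom.gene_ids))

    # modules -------------------------------------------------------------
    def _modules():
        dend = cluster_dendrogram(tom)
        assign = dynamic_tree_cut(
            dend, config.min_module_size, config.cut_height_quantile, config.deep_split
        )
        return dend, assign

    dend, assign = guard("modules", _modules)
    (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
    groups: dict[str, tuple[int, list[str]]] = {}
    for reg in config.regulators:
        try:
            groups[reg] = regulator_group(assign, reg, filtered_ids=removed)
        except KeyError as exc:
            raise PipelineError("regulator_groups", "regulator_missing", str(exc)) from exc
    mod_df = assign.as_frame()
    for reg, (label, _) in groups.items():
        mod_df[f"in_{reg}_group"] = (mod_df["module"] == label) & (label != 0)
    mod_path = out / "modules.tsv"
    mod_df.to_csv(mod_path, sep="\t", index=False)
    record("modules", [mod_path, out / "dendrogram.nwk"],
           n_modules=assign.n_modules, variant=assign.variant)

    # regulator groups ----------------------------------------------------
    grp_rows = [
        {"regulator": reg, "module": label, "n_members": len(members)}
        for reg, (label, members) in groups.items()
    ]
    grp_path = out / "regulator_groups.tsv"
    pd.DataFrame(grp_rows, columns=["regulator", "module", "n_members"]).to_csv(
        grp_path, sep="\t", index=False
    )
    record("regulator_groups", [grp_path],
           **{reg: label for reg, (label, _) in groups.items()})

    # annotations (shared by hrr node attrs, topology and enrichment) -----
    annotations = None
    if config.go_path is not None or config.cazyme_path is not None:
        annotations = guard(
            "enrichment",
            lambda: AnnotationTable.from_tsvs(
                config.go_path, config.cazyme_path, config.tf_path,
                config.transporter_path, config.ko_path, config.de_path,
            ),
            code="bad_annotation",
        )

    # hrr -----------------------------------------------------------------
    net = guard(
        "hrr",
        lambda: build_hrr_network(
            corr, config.r_threshold, config.max_rank, config.absolute_r,
            assign, annotations,
        ),
    )
    edges_path = out / "hrr_edges.tsv"
    edge_table(net).to_csv(edges_path, sep="\t", index=False)
    graphml_path = out / "hrr_network.graphml"
    write_graphml(net, graphml_path)
    record("hrr", [edges_path, graphml_path],
           n_nodes=net.number_of_nodes(), n_edges=net.number_of_edges())

    # topology ------------------------------------------------------------
    topo_outputs = []

    def _topology():
        for reg, (label, _) in groups.items():
            sub = module_subnetwork(net, assign, label) if label != 0 else net.subgraph([reg])
            if sub.number_of_nodes():
                deg = degree_and_hubs(sub)
                p = out / f"degree_{reg}_group.tsv"
                deg.to_csv(p, sep="\t", index=False)
                topo_outputs.append(p)
            report = first_neighbors(net, reg, assign, annotations)
            p = out / f"first_neighbors_{reg}.tsv"
            report.table.to_csv(p, sep="\t", index=False)
            topo_outputs.append(p)
        targets = list(config.cazyme_targets)
        if not targets and annotations is not None:
            targets = sorted(g for g in annotations.cazyme_family if g in net)
        if config.regulators and targets:
            paths_df = regulator_cazyme_matrix(net, config.regulators, targets)
            p = out / "shortest_paths.tsv"
            paths_df.to_csv(p, sep="\t", index=False)
            topo_outputs.append(p)
            return {"n_targets": len(targets)}
        return {"n_targets": 0}

    topo_summary = guard("topology", _topology)
    record("topology", topo_outputs, **topo_summary)

    # enrichment ----------------------------------------------------------
    enr_outputs = []

    def _enrichment():
        if not config.run_enrichment or annotations is None:
            return {"skipped": True}
        background = matrix.gene_ids
        n_terms = {}
        for reg, (label, members) in groups.items():
            enr = go_enrichment(members, background, annotations,
                                config.alpha, config.bh_correction)
            p = out / f"enrichment_{reg}_group.tsv"
            enr.to_csv(p, sep="\t", index=False)
            enr_outputs.append(p)
            n_terms[reg] = int(enr["enriched"].sum()) if len(enr) else 0
            for cat in ("cazyme_family", "cazyme_class", "tf_class",
                        "transporter_class", "ko_pathway_class"):
                tally = category_tally(members, annotations, cat)
                p = out / f"tally_{reg}_{cat}.tsv"
                pd.DataFrame(
                    sorted(tally.items()), columns=["value", "count"]
                ).to_csv(p, sep="\t", index=False)
                enr_outputs.append(p)
        de_rows = []
        if annotations.de_status:
            for reg, (label, members) in groups.items():
                up, down, total = de_overlap(members, annotations)
                de_rows.append({"group": f"{reg}_group", "n_up": up,
                                "n_down": down, "n_total": total})
        if de_rows:
            p = out / "de_overlap.tsv"
            pd.DataFrame(de_rows).to_csv(p, sep="\t", index=False)
            enr_outputs.append(p)
        return {"n_enriched": n_terms}

    enr_summary = guard("enrichment", _enrichment)
    record("enrichment", enr_outputs, **enr_summary)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
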