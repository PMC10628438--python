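"""End-to-end orchestration: counts -> representative cells -> co-expression
modules -> module selection -> regulatory network -> drug overlay.

Each stage writes its outputs as plain-text tables so any stage can be
re-run in isolation, and a JSON run report records versions, parameters,
seeds, per-stage counts, and warnings.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import coexpression as cx
from . import drugmap, grn, pseudocells
from .io_formats import (
    ExpressionMatrix,
    read_drug_table,
    read_expression,
    read_metadata,
    read_motif_db,
    read_tf_list,
    write_edge_table,
    write_expression_tsv,
    write_graphml,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    expression_path: str
    out_dir: str
    expression_fmt: str = "tsv"
    orientation: str = "cells_by_genes"
    metadata_path: str | None = None
    metadata_key: str = "cell_id"
    tf_list_path: str | None = None
    motif_ranks_path: str | None = None
    motif_annotation_path: str | None = None
    drug_table_path: str | None = None

    normalize: bool = True
    group_column: str = "group"
    n_subclusters: int = 10
    embedding_dims: int = 50

    correlation_method: str = "bicor"
    network_type: str = "signed"
    power: int | None = None  # None = auto-select
    r2_cut: float = 0.85
    min_module_size: int = 30
    merge_cut: float = 0.25
    hub_top_frac: float = 0.10

    select_module: int | None = None
    select_trait: str | None = None
    select_gene: str | None = None

    rank_threshold_frac: float = 0.05
    nes_cut: float = 3.0
    top_k_per_tf: int = 50
    keep_unannotated: bool = False

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("expression_path", "metadata_path", "tf_list_path",
                     "motif_ranks_path", "motif_annotation_path",
                     "drug_table_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


@dataclass
class StageOutputs:
    modules: cx.ModuleSet | None = None
    trait_table: pd.DataFrame | None = None
    grn_edges: pd.DataFrame | None = None
    report: dict[str, Any] = field(default_factory=dict)


def select_module(
    modules: cx.ModuleSet,
    trait_table: pd.DataFrame | None,
    explicit: int | None,
    trait: str | None,
    gene: str | None = None,
) -> int:
    """Pick the module to carry into GRN inference.

    An explicit module id wins; then the module containing a named gene of
    interest; otherwise the module with the highest absolute trait
    correlation for the named trait.
    """
    if explicit is not None:
        if explicit not in modules.module_ids:
            raise ValueError(f"module {explicit} does not exist; have {modules.module_ids}")
        return explicit
    if gene is not None:
        if gene not in modules.genes:
            raise ValueError(f"gene {gene!r} not in the network")
        lab = int(modules.labels[modules.genes.index(gene)])
        if lab == cx.GREY:
            raise ValueError(f"gene {gene!r} is unassigned (grey)")
        return lab
    if trait is None:
        raise ValueError("a module id, a gene of interest, or a trait name is required")
    if trait_table is None:
        raise ValueError("trait correlations not computed")
    sub = trait_table[trait_table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not found; have {sorted(trait_table['trait'].unique())}")
    best = sub.loc[sub["rho"].abs().idxmax(), "module"]
    return int(str(best).lstrip("M"))


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns the run report dict.

    Aborts with the failing stage's name attached to the exception.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "parameters": asdict(config),
        "stages": {},
        "warnings": [],
    }
    stage = "load"
    try:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            expr = read_expression(config.expression_path, config.expression_fmt,
                                   config.orientation)
            if config.metadata_path:
                meta = read_metadata(config.metadata_path, config.metadata_key)
                expr.attach_metadata(meta)
            report["stages"]["load"] = {"n_cells": expr.n_cells, "n_genes": expr.n_genes}

            stage = "pseudocells"
            work = pseudocells.normalize_log1p(expr) if config.normalize else expr
            pc = pseudocells.make_representative_cells(
                work, config.group_column, config.n_subclusters,
                seed=config.seed, embedding_dims=config.embedding_dims,
            )
            rep = pc.expr
            write_expression_tsv(rep, out / "representative_cells.tsv")
            pc.assignment.to_csv(out / "pseudocell_assignment.tsv", sep="\t")
            report["stages"]["pseudocells"] = {
                "n_representative_cells": rep.n_cells,
                "n_subclusters": pc.n_subclusters,
            }

            stage = "gcn"
            cor = cx.correlation_matrix(rep.values, rep.gene_ids,
                                        method=config.correlation_method)
            if config.power is None:
                pick = cx.pick_soft_threshold(cor, config.network_type,
                                              r2_cut=config.r2_cut)
                beta = pick.beta
                pick.table.to_csv(out / "soft_threshold.tsv", sep="\t", index=False)
            else:
                beta = config.power
            adj = cx.adjacency(cor, config.network_type, beta)
            tom = cx.tom_similarity(adj)
            modules = cx.detect_modules(
                tom, rep.to_frame(), min_module_size=config.min_module_size,
                merge_cut=config.merge_cut,
            )
            modules.kim = cx.intramodular_connectivity(adj, modules.labels)
            if modules.eigengenes is not None:
                modules.kme = cx.module_membership(
                    rep.values, rep.gene_ids, modules.labels, modules.eigengenes,
                    method=config.correlation_method,
                )
                for m in modules.module_ids:
                    modules.hubs[m] = cx.detect_hubs(
                        modules.module_genes(m), modules.kim, modules.kme,
                        top_frac=config.hub_top_frac,
                    )
                modules.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
                trait_table = cx.module_trait_correlation(
                    modules.eigengenes, rep.metadata.drop(columns=["size"],
                                                          errors="ignore"),
                )
                trait_table.to_csv(out / "module_trait.tsv", sep="\t", index=False)
            else:
                trait_table = None
            modules.to_frame().to_csv(out / "modules.tsv", sep="\t", index=False)
            sizes = {int(m): len(modules.module_genes(m)) for m in modules.module_ids}
            report["stages"]["gcn"] = {
                "beta": int(beta),
                "n_modules": len(modules.module_ids),
                "module_sizes": sizes,
                "n_grey": int((modules.labels == cx.GREY).sum()),
            }

            stage = "grn"
            grn_edges = None
            if config.tf_list_path and config.motif_ranks_path and \
                    config.motif_annotation_path:
                chosen = select_module(modules, trait_table, config.select_module,
                                       config.select_trait, config.select_gene)
                module_genes = modules.module_genes(chosen)
                tf_list = read_tf_list(config.tf_list_path)
                tfs = grn.scan_tfs(module_genes, tf_list)
                sub_expr = rep.to_frame()[module_genes]
                candidates = grn.infer_candidates(
                    sub_expr, tfs, module_genes, seed=config.seed,
                    top_k_per_tf=config.top_k_per_tf,
                )
                write_edge_table(grn.edges_to_frame(candidates),
                                 out / "candidate_edges.tsv")
                db = read_motif_db(config.motif_ranks_path,
                                   config.motif_annotation_path)
                tf_targets = {}
                for e in candidates:
                    tf_targets.setdefault(e.tf, []).append(e.target)
                enr = grn.motif_enrichment(
                    tf_targets, db, rank_threshold_frac=config.rank_threshold_frac,
                    nes_cut=config.nes_cut,
                )
                pd.DataFrame(
                    [{"tf": e.tf, "motif_id": e.motif_id, "auc": e.auc,
                      "nes": e.nes, "enriched": e.enriched} for e in enr]
                ).to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
                net = grn.prune_to_grn(candidates, enr,
                                       keep_unannotated=config.keep_unannotated)
                grn_edges = net.edges
                write_edge_table(grn_edges.drop(columns=["unannotated"]),
                                 out / "grn_edges.tsv")
                report["stages"]["grn"] = {
                    "selected_module": int(chosen),
                    "n_tfs": len(tfs),
                    "n_candidate_edges": len(candidates),
                    "n_retained_edges": int(len(grn_edges)),
                    "unannotated_tfs": net.unannotated_tfs,
                }

            stage = "drugs"
            if config.drug_table_path and grn_edges is not None:
                table = read_drug_table(config.drug_table_path)
                net_genes = sorted(set(grn_edges["tf"]) | set(grn_edges["target"]))
                assoc, summary = drugmap.map_drugs(net_genes, table)
                assoc.to_csv(out / "drug_associations.tsv", sep="\t", index=False)
                combined = drugmap.build_combined_network(
                    grn_edges, assoc, tf_nodes=set(grn_edges["tf"]),
                )
                write_graphml(combined, out / "combined_network.graphml")
                report["stages"]["drugs"] = {
                    "n_drugs": summary.n_drugs,
                    "n_targeted_genes": summary.n_targeted_genes,
                    "provenance": summary.provenance,
                }
            report["warnings"] = sorted({str(w.message) for w in wrec})
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
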