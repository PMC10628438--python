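"""Drug-target overlay on a gene or regulatory network.

Drug associations come from a versioned local drug-target snapshot (a TSV
with drug_id, drug_name, gene_symbol, action, source); matching is an exact
gene-symbol join, and the snapshot's provenance string is echoed into every
output so results stay reproducible against a pinned table. The combined
network holds three node types — genes, TFs, and drugs — with directed
TF->gene regulation edges and undirected drug-gene links.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import networkx as nx
import pandas as pd

from .io_formats import DrugTargetTable

DRUG_PREFIX = "drug:"


@dataclass
class DrugMappingSummary:
    n_drugs: int
    n_targeted_genes: int
    provenance: str


def map_drugs(
    genes: Sequence[str], table: DrugTargetTable
) -> tuple[pd.DataFrame, DrugMappingSummary]:
    """All drug-target records whose gene symbol is in ``genes``.

    Returns the association table and a summary counting distinct drugs and
    distinct targeted genes.
    """
    if len(table) == 0:
        raise ValueError("drug-target table is empty")
    gene_set = set(genes)
    hits = table.records[table.records["gene_symbol"].isin(gene_set)].copy()
    hits = hits.sort_values(["drug_id", "gene_symbol"], kind="mergesort").reset_index(drop=True)
    summary = DrugMappingSummary(
        n_drugs=int(hits["drug_id"].nunique()),
        n_targeted_genes=int(hits["gene_symbol"].nunique()),
        provenance=table.provenance,
    )
    return hits, summary


def build_combined_network(
    network_edges: pd.DataFrame,
    associations: pd.DataFrame,
    tf_nodes: Sequence[str] = (),
    coexpression_edges: pd.DataFrame | None = None,
) -> nx.DiGraph:
    """Merge regulation, co-expression, and drug links into one typed graph.

    ``network_edges`` needs columns (tf, target) and optionally importance;
    ``associations`` needs (drug_id, drug_name, gene_symbol). Drug node ids
    are prefixed so they can never collide with gene symbols. Drug and
    co-expression links are stored as reciprocal directed edges so the
    graph exports cleanly to GraphML with a single edge default.
    """
    g = nx.DiGraph()
    tf_set = set(tf_nodes)
    if {"tf", "target"}.issubset(network_edges.columns):
        tf_set |= set(network_edges["tf"])
        for _, row in network_edges.iterrows():
            for node in (row["tf"], row["target"]):
                g.add_node(node, node_type="gene")
            attrs = {"edge_type": "regulation"}
            if "importance" in network_edges.columns:
                attrs["weight"] = float(row["importance"])
            for extra in ("motif_id", "nes"):
                if extra in network_edges.columns and pd.notna(row[extra]):
                    attrs[extra] = row[extra]
            g.add_edge(row["tf"], row["target"], **attrs)
    if coexpression_edges is not None:
        for _, row in coexpression_edges.iterrows():
            for node in (row["gene1"], row["gene2"]):
                g.add_node(node, node_type="gene")
            g.add_edge(row["gene1"], row["gene2"], edge_type="coexpression",
                       weight=float(row.get("correlation", 1.0)))
            g.add_edge(row["gene2"], row["gene1"], edge_type="coexpression",
                       weight=float(row.get("correlation", 1.0)))
    for n in tf_set:
        if n in g.nodes:
            g.nodes[n]["node_type"] = "tf"
    network_genes = set(g.nodes)
    for _, row in associations.iterrows():
        gene = row["gene_symbol"]
        if gene not in network_genes:
            raise ValueError(f"association target {gene!r} is not in the network")
        drug_node = DRUG_PREFIX + str(row["drug_id"])
        g.add_node(drug_node, node_type="drug", drug_name=str(row["drug_name"]))
        g.add_edge(drug_node, gene, edge_type="drug_target",
                   action=str(row.get("action", "")))
        g.add_edge(gene, drug_node, edge_type="drug_target",
                   action=str(row.get("action", "")))
    return g


def load_example_drug_fixture() -> tuple[list[str], DrugTargetTable]:
    """Packaged synthetic example: a 40-gene network plus a drug-target
    snapshot whose join yields 20 distinct drugs over 8 targeted genes.

    Both files are synthetic fixtures shipped with the package; they mimic
    the shape of a repurposing query without reproducing any real database.
    """
    data = resources.files("scgrnet") / "data"
    genes = [
        line.strip()
        for line in (data / "example_network_genes.txt").read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    import io

    text = (data / "example_drug_table.tsv").read_text()
    first = text.splitlines()[0]
    prov = first.lstrip("# ").strip() if first.startswith("#") else "packaged fixture"
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#", dtype=str).fillna("")
    return genes, DrugTargetTable(df, provenance=prov)
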