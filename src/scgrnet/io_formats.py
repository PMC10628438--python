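"""Readers and writers for the plain-text formats the pipeline touches.

All readers validate and reject malformed input rather than repairing it.
The canonical in-memory orientation for expression data is cells in rows,
genes in columns. Identifiers are case-sensitive and matched exactly.

TSV dialect: tab-separated, UTF-8; lines starting with ``#`` are comments
and skipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

logger = logging.getLogger(__name__)

Orientation = Literal["cells_by_genes", "genes_by_cells"]


def _find_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with attached per-cell metadata.

    ``values`` is a float array with cells in rows; ``metadata`` is indexed
    by ``cell_ids`` in the same order. Raw counts and normalized values are
    both allowed; nothing here assumes a scale.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix has {n_genes} gene columns but {len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n_cells} cell rows but {len(self.cell_ids)} cell ids"
            )
        dup_g = _find_duplicates(self.gene_ids)
        if dup_g:
            raise ValueError(f"duplicate gene ids: {dup_g}")
        dup_c = _find_duplicates(self.cell_ids)
        if dup_c:
            raise ValueError(f"duplicate cell ids: {dup_c}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain non-finite entries")
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            self.metadata = self.metadata.loc[self.cell_ids]

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.cell_ids, name="cell_id"),
            columns=pd.Index(self.gene_ids, name="gene"),
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not present: {missing}")
        cols = [idx[g] for g in genes]
        return ExpressionMatrix(
            self.values[:, cols], list(genes), self.cell_ids, self.metadata.copy()
        )

    def attach_metadata(self, meta: pd.DataFrame) -> None:
        """Join a per-cell table (indexed by cell id); unmatched matrix cells error,
        unmatched metadata rows are dropped silently (reported at read time)."""
        missing = [c for c in self.cell_ids if c not in meta.index]
        if missing:
            raise ValueError(f"metadata missing for cells: {missing[:10]}")
        self.metadata = meta.loc[self.cell_ids].copy()


@dataclass
class MotifRankingDB:
    """Whole-genome motif rankings: one rank permutation of 1..G per motif.

    Rank 1 is the best-scoring regulatory region for that motif. ``motif2tf``
    links motif ids to the transcription factors they may represent.
    """

    motif_ids: list[str]
    gene_ids: list[str]
    ranks: np.ndarray  # motifs x genes, int
    motif2tf: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=int)
        g = len(self.gene_ids)
        if self.ranks.shape != (len(self.motif_ids), g):
            raise ValueError("rank matrix shape does not match motif/gene ids")
        expected = np.arange(1, g + 1)
        for i, m in enumerate(self.motif_ids):
            if not np.array_equal(np.sort(self.ranks[i]), expected):
                raise ValueError(f"motif {m}: ranks not a permutation of 1..{g}")
        known = set(self.motif_ids)
        for motif, tf in self.motif2tf:
            if motif not in known:
                raise ValueError(f"annotation references unknown motif {motif!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def motifs_for_tf(self, tf: str) -> list[str]:
        return sorted(m for m, t in self.motif2tf if t == tf)


@dataclass
class DrugTargetTable:
    """Local drug-target snapshot: (drug_id, drug_name, gene_symbol, action, source)."""

    records: pd.DataFrame
    provenance: str = "unversioned local snapshot"

    REQUIRED = ("drug_id", "drug_name", "gene_symbol", "action", "source")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"drug table missing columns: {missing}")
        rec = self.records
        if (rec["drug_id"].astype(str).str.len() == 0).any() or rec["drug_id"].isna().any():
            raise ValueError("drug table contains empty drug_id")
        if (rec["gene_symbol"].astype(str).str.len() == 0).any() or rec["gene_symbol"].isna().any():
            raise ValueError("drug table contains empty gene_symbol")
        dup = rec.duplicated(subset=["drug_id", "gene_symbol"])
        if dup.any():
            pairs = rec.loc[dup, ["drug_id", "gene_symbol"]].values.tolist()
            raise ValueError(f"duplicate (drug_id, gene_symbol) pairs: {pairs[:5]}")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_id_file(path: Path) -> list[str]:
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.append(line.split("\t")[0])
    return ids


def read_expression(
    path: str | Path,
    fmt: Literal["mtx", "csv", "tsv"] = "tsv",
    orientation: Orientation = "cells_by_genes",
) -> ExpressionMatrix:
    """Read an expression matrix from MatrixMarket or dense CSV/TSV.

    For ``mtx``, sidecar files ``genes.tsv`` and ``barcodes.tsv`` must sit
    next to the matrix file. Dense files carry cell/gene ids in the first
    column and header row. ``genes_by_cells`` input is transposed to the
    canonical cells-in-rows layout.
    """
    path = Path(path)
    if fmt == "mtx":
        mat = np.asarray(mmread(path).todense(), dtype=float)
        genes = _read_id_file(path.parent / "genes.tsv")
        cells = _read_id_file(path.parent / "barcodes.tsv")
        if orientation == "genes_by_cells":
            mat = mat.T
        n_cells, n_genes = mat.shape
        if n_genes != len(genes) or n_cells != len(cells):
            raise ValueError(
                f"matrix is {n_cells}x{n_genes} but sidecars list "
                f"{len(cells)} cells and {len(genes)} genes"
            )
        return ExpressionMatrix(mat, genes, cells)
    if fmt not in ("csv", "tsv"):
        raise ValueError(f"unknown format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    # pandas mangles duplicate header names (g1 -> g1.1); check them raw
    with open(path, encoding="utf-8") as fh:
        header = next(
            line for line in fh if line.strip() and not line.startswith("#")
        )
    header_ids = header.rstrip("\n").split(sep)[1:]
    dups = _find_duplicates(header_ids)
    if dups:
        raise ValueError(f"duplicate column ids in {path}: {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if orientation == "genes_by_cells":
        df = df.T
    return ExpressionMatrix(
        df.to_numpy(dtype=float), [str(c) for c in df.columns], [str(i) for i in df.index]
    )


def read_metadata(path: str | Path, key_column: str = "cell_id") -> pd.DataFrame:
    """Read a per-cell metadata TSV keyed by ``key_column``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if key_column not in df.columns:
        raise ValueError(f"metadata file lacks key column {key_column!r}")
    if df[key_column].duplicated().any():
        dups = df.loc[df[key_column].duplicated(), key_column].tolist()
        raise ValueError(f"duplicate {key_column} rows in metadata: {dups}")
    return df.set_index(key_column)


def align_metadata(meta: pd.DataFrame, cell_ids: Sequence[str]) -> pd.DataFrame:
    """Align metadata to a cell-id list; warn about metadata-only cells."""
    extra = [c for c in meta.index if c not in set(cell_ids)]
    if extra:
        warnings.warn(
            f"{len(extra)} metadata rows have no matching cell and will be "
            f"dropped at join time: {extra[:5]}",
            stacklevel=2,
        )
    missing = [c for c in cell_ids if c not in meta.index]
    if missing:
        raise ValueError(f"cells without metadata: {missing[:10]}")
    return meta.loc[list(cell_ids)]


def read_tf_list(path: str | Path) -> list[str]:
    """Read a plain-text TF symbol list, one per line, preserving order."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            sym = line.strip()
            if not sym or sym.startswith("#"):
                continue
            if sym not in seen:
                out.append(sym)
                seen.add(sym)
    if not out:
        raise ValueError(f"TF list {path} is empty")
    return out


def read_motif_db(ranks_path: str | Path, annotation_path: str | Path) -> MotifRankingDB:
    """Load the motif rank matrix (motifs x genes TSV) and motif→TF annotation."""
    ranks = pd.read_csv(ranks_path, sep="\t", index_col=0, comment="#")
    ann = pd.read_csv(annotation_path, sep="\t", comment="#")
    for col in ("motif_id", "tf_symbol"):
        if col not in ann.columns:
            raise ValueError(f"annotation file lacks column {col!r}")
    motif2tf = {(str(m), str(t)) for m, t in zip(ann["motif_id"], ann["tf_symbol"])}
    return MotifRankingDB(
        motif_ids=[str(m) for m in ranks.index],
        gene_ids=[str(g) for g in ranks.columns],
        ranks=ranks.to_numpy(dtype=int),
        motif2tf=motif2tf,
    )


def read_drug_table(path: str | Path, provenance: str | None = None) -> DrugTargetTable:
    """Load a drug-target TSV snapshot.

    The first comment line of the file, if any, is kept as the provenance
    string and echoed into every downstream output.
    """
    path = Path(path)
    prov = provenance
    if prov is None:
        with open(path, encoding="utf-8") as fh:
            first = fh.readline().strip()
        prov = first.lstrip("# ").strip() if first.startswith("#") else f"file:{path.name}"
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    return DrugTargetTable(df, provenance=prov)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t")


def write_expression_mtx(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    mmwrite(str(path), coo_matrix(expr.values))
    with open(path.parent / "genes.tsv", "w", encoding="utf-8") as fh:
        fh.write("\n".join(expr.gene_ids) + "\n")
    with open(path.parent / "barcodes.tsv", "w", encoding="utf-8") as fh:
        fh.write("\n".join(expr.cell_ids) + "\n")


def write_edge_table(edges: pd.DataFrame, path: str | Path) -> None:
    """Write an edge table TSV, sorted lexicographically by its first column
    (then the second) for byte-stable output."""
    cols = list(edges.columns)
    out = edges.sort_values(cols[: min(2, len(cols))], kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


VALID_NODE_TYPES = {"gene", "tf", "drug"}


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """Write a typed network to GraphML.

    Every node must carry a ``node_type`` attribute in {gene, tf, drug};
    edges keep whatever scalar attributes they carry (weights, evidence).
    """
    for n, data in graph.nodes(data=True):
        nt = data.get("node_type")
        if nt not in VALID_NODE_TYPES:
            raise ValueError(f"node {n!r} has invalid node_type {nt!r}")
    for u, v in graph.edges():
        if u not in graph.nodes or v not in graph.nodes:
            raise ValueError(f"dangling edge ({u!r}, {v!r})")
    nx.write_graphml(graph, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
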