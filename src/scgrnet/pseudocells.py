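"""Representative cells ("pseudo-cells") by within-group sub-clustering.

Single-cell matrices are tall and sparse; thousands of cells per cell type
make gene-gene correlation both noisy and expensive. Each cell group
(typically a cell type) is therefore partitioned into N sub-clusters of
similar cells, and each sub-cluster is collapsed into one representative
cell by per-gene averaging. Every retained group contributes exactly N
representative cells, so groups stay balanced downstream.

Sub-clustering is k-means (k = N) on the leading principal components of
the group's z-scored expression, with a fixed seed for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PseudocellResult:
    expr: ExpressionMatrix
    assignment: pd.DataFrame  # index cell_id, columns: group, subcluster, pseudocell_id
    sizes: pd.Series  # pseudocell_id -> member count
    n_subclusters: int


def normalize_log1p(expr: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Library-size normalization (counts per ``target_sum``) followed by log1p."""
    totals = expr.values.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    vals = np.log1p(expr.values / totals * target_sum)
    return ExpressionMatrix(vals, expr.gene_ids, expr.cell_ids, expr.metadata.copy())


def _subcluster_group(
    mat: np.ndarray, n_subclusters: int, seed: int, embedding_dims: int
) -> np.ndarray:
    """k-means labels for one group's cells; retries on empty clusters."""
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    z = (mat - mu) / sd
    n_comp = min(embedding_dims, mat.shape[0] - 1, mat.shape[1])
    n_comp = max(n_comp, 1)
    emb = PCA(n_components=n_comp, random_state=seed).fit_transform(z)
    for attempt in range(5):
        km = KMeans(
            n_clusters=n_subclusters, init="k-means++", n_init=10,
            random_state=seed + attempt,
        )
        labels = km.fit_predict(emb)
        if len(np.unique(labels)) == n_subclusters:
            return labels
    raise RuntimeError(
        f"k-means produced an empty sub-cluster in 5 attempts (k={n_subclusters}, "
        f"n={mat.shape[0]})"
    )


def make_representative_cells(
    expr: ExpressionMatrix,
    group_column: str,
    n_subclusters: int,
    seed: int = 0,
    embedding_dims: int = 50,
) -> PseudocellResult:
    """Collapse each cell group into ``n_subclusters`` representative cells.

    Groups with fewer than ``n_subclusters`` cells are dropped with a
    warning, so every group in the output is represented by the same number
    of cells. Averaging happens on whatever scale ``expr`` is in; callers
    normally pass log-normalized data (see :func:`normalize_log1p`).
    """
    if n_subclusters < 1:
        raise ValueError(f"n_subclusters must be >= 1, got {n_subclusters}")
    if group_column not in expr.metadata.columns:
        raise KeyError(f"metadata has no column {group_column!r}")

    groups = expr.metadata[group_column].astype(str)
    rep_rows: list[np.ndarray] = []
    rep_ids: list[str] = []
    rep_meta: list[dict] = []
    assign_rows: list[dict] = []
    sizes: dict[str, int] = {}

    for g_idx, group in enumerate(sorted(groups.unique())):
        mask = (groups == group).to_numpy()
        n_cells = int(mask.sum())
        if n_cells < n_subclusters:
            logger.warning(
                "group %r has %d cells < N=%d sub-clusters; dropped",
                group, n_cells, n_subclusters,
            )
            continue
        sub = expr.values[mask]
        cell_ids = [c for c, m in zip(expr.cell_ids, mask) if m]
        labels = _subcluster_group(sub, n_subclusters, seed + 7919 * g_idx, embedding_dims)
        for k in range(n_subclusters):
            members = labels == k
            pc_id = f"{group}|{k}"
            rep_rows.append(sub[members].mean(axis=0))
            rep_ids.append(pc_id)
            rep_meta.append({group_column: group, "size": int(members.sum())})
            sizes[pc_id] = int(members.sum())
        for cid, lab in zip(cell_ids, labels):
            assign_rows.append(
                {"cell_id": cid, "group": group, "subcluster": int(lab),
                 "pseudocell_id": f"{group}|{int(lab)}"}
            )

    if not rep_rows:
        raise ValueError("no group has enough cells for the requested N")

    meta = pd.DataFrame(rep_meta, index=pd.Index(rep_ids, name="cell_id"))
    rep = ExpressionMatrix(np.vstack(rep_rows), expr.gene_ids, rep_ids, meta)
    assignment = pd.DataFrame(assign_rows).set_index("cell_id")
    return PseudocellResult(
        expr=rep,
        assignment=assignment,
        sizes=pd.Series(sizes, name="size"),
        n_subclusters=n_subclusters,
    )
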