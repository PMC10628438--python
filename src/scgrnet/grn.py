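"""Directed regulatory networks from a co-expression module.

A selected module is converted into a transcription-factor -> target-gene
graph in three steps. First the module's genes are scanned against a TF
catalogue. Then, for every target gene, a stochastic gradient-boosted
regression ensemble predicts its expression from the TF expressions; the
total impurity-reduction (gain) a TF contributes across all its splits is
that TF's importance for the target, and positive-importance pairs become
candidate edges. Finally each TF's candidate target set is tested for
cis-regulatory motif enrichment against a whole-genome ranking database:
the recovery AUC of the set within the top fraction of each motif's
ranking is standardized across all motifs into a normalized enrichment
score (NES), and only edges whose target falls in the leading edge of an
enriched motif annotated to the TF survive.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor

from .io_formats import MotifRankingDB

logger = logging.getLogger(__name__)


@dataclass
class BoostingParams:
    """Hyperparameters of the per-target boosted regression ensemble."""

    n_trees_max: int = 500
    learning_rate: float = 0.01
    subsample: float = 0.9
    max_features: str | float = "sqrt"
    early_stop_window: int = 25


@dataclass
class CandidateEdge:
    tf: str
    target: str
    importance: float

    def __post_init__(self) -> None:
        if self.tf == self.target:
            raise ValueError("self-regulation edges are not allowed")
        if self.importance < 0:
            raise ValueError("importance must be non-negative")


@dataclass
class MotifEnrichment:
    tf: str
    motif_id: str
    auc: float
    nes: float
    enriched: bool
    leading_edge: frozenset[str]


@dataclass
class RegulatoryNetwork:
    edges: pd.DataFrame  # tf, target, importance, motif_id, auc, nes
    unannotated_tfs: list[str] = field(default_factory=list)


def scan_tfs(module_genes: Sequence[str], tf_list: Sequence[str]) -> list[str]:
    """Transcription factors present in a module, in module-gene order."""
    tfs = set(tf_list)
    found = [g for g in module_genes if g in tfs]
    if not found:
        raise ValueError("module contains no known TFs")
    return found


def _early_stop_monitor(window: int):
    """Stop boosting when mean out-of-bag improvement over the last
    ``window`` rounds is <= 0."""

    def monitor(i: int, est: GradientBoostingRegressor, locals_: dict) -> bool:
        if i + 1 < window:
            return False
        recent = est.oob_improvement_[i + 1 - window: i + 1]
        return bool(np.mean(recent) <= 0)

    return monitor


def _gain_importances(est: GradientBoostingRegressor, n_features: int) -> np.ndarray:
    """Total (unnormalized) impurity reduction per feature over all trees."""
    total = np.zeros(n_features)
    for stage in est.estimators_:
        tree = stage[0].tree_
        total += tree.compute_feature_importances(normalize=False)
    return total


def infer_candidates(
    expr: pd.DataFrame,
    tfs: Sequence[str],
    targets: Sequence[str],
    params: BoostingParams | None = None,
    seed: int = 0,
    top_k_per_tf: int | None = 50,
) -> list[CandidateEdge]:
    """Candidate TF -> target edges from boosted regression importances.

    ``expr`` is a samples x genes frame containing all TFs and targets.
    Each target is regressed on all TFs except itself; a TF's importance is
    its summed split gain. Edges with positive importance are kept, sorted
    by importance descending, and optionally capped at ``top_k_per_tf``
    strongest edges per TF before motif testing.
    """
    params = params or BoostingParams()
    if expr.shape[0] < 10:
        raise ValueError(f"need >= 10 samples for GRN inference, got {expr.shape[0]}")
    missing = [g for g in list(tfs) + list(targets) if g not in expr.columns]
    if missing:
        raise KeyError(f"genes absent from expression: {missing[:5]}")

    rng = np.random.default_rng(seed)
    edges: list[CandidateEdge] = []
    for target in targets:
        predictors = [t for t in tfs if t != target]
        if not predictors:
            continue
        y = expr[target].to_numpy(dtype=float)
        if np.all(y == y[0]):
            warnings.warn(f"target {target!r} is constant; skipped", stacklevel=2)
            continue
        X = expr[predictors].to_numpy(dtype=float)
        est = GradientBoostingRegressor(
            n_estimators=params.n_trees_max,
            learning_rate=params.learning_rate,
            subsample=params.subsample,
            max_features=params.max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        est.fit(X, y, monitor=_early_stop_monitor(params.early_stop_window))
        gains = _gain_importances(est, len(predictors))
        if not np.any(gains > 0):
            warnings.warn(f"no informative TF for target {target!r}", stacklevel=2)
        for tf, g in zip(predictors, gains):
            if g > 0:
                edges.append(CandidateEdge(tf=tf, target=target, importance=float(g)))

    edges.sort(key=lambda e: (-e.importance, e.tf, e.target))
    if top_k_per_tf is not None:
        kept: list[CandidateEdge] = []
        per_tf: dict[str, int] = {}
        for e in edges:
            c = per_tf.get(e.tf, 0)
            if c < top_k_per_tf:
                kept.append(e)
                per_tf[e.tf] = c + 1
        edges = kept
    return edges


def edges_to_frame(edges: Sequence[CandidateEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"tf": e.tf, "target": e.target, "importance": e.importance} for e in edges],
        columns=["tf", "target", "importance"],
    )


def recovery_auc(ranks: np.ndarray, member_ranks: np.ndarray, top_t: int) -> float:
    """Normalized recovery AUC of a gene set within the top ``top_t`` ranks.

    With recovery count c(r) = |{g in S : rank(g) <= r}|,
    AUC = sum_{r=1..T} c(r) / (T * |S|); a set occupying ranks 1..|S|
    approaches 1, a set entirely below rank T scores 0.
    """
    n = len(member_ranks)
    if n == 0:
        raise ValueError("empty gene set")
    inside = member_ranks[member_ranks <= top_t]
    # each member at rank r contributes (T - r + 1) to sum over r of c(r)
    return float((top_t - inside + 1).sum()) / (top_t * n)


def motif_enrichment(
    tf_targets: Mapping[str, Sequence[str]],
    db: MotifRankingDB,
    rank_threshold_frac: float = 0.05,
    nes_cut: float = 3.0,
) -> list[MotifEnrichment]:
    """Cis-regulatory motif enrichment of each TF's candidate target set.

    For each TF the recovery AUC of its target set is computed for every
    motif in the database; the NES of a motif is its AUC standardized
    against the AUC distribution over all motifs for that same set. Motifs
    annotated to the TF with NES >= ``nes_cut`` are enriched; their leading
    edge is the subset of targets ranked within the top threshold region.
    """
    gene_pos = {g: j for j, g in enumerate(db.gene_ids)}
    top_t = math.ceil(rank_threshold_frac * db.n_genes)
    results: list[MotifEnrichment] = []
    for tf, targets in tf_targets.items():
        in_db = [t for t in targets if t in gene_pos]
        dropped = [t for t in targets if t not in gene_pos]
        if dropped:
            warnings.warn(
                f"{len(dropped)} targets of {tf!r} absent from motif DB and dropped",
                stacklevel=2,
            )
        if not in_db:
            logger.info("TF %r has no targets in the motif DB; skipped", tf)
            continue
        cols = [gene_pos[t] for t in in_db]
        sub = db.ranks[:, cols]  # motifs x |S|
        inside = np.where(sub <= top_t, top_t - sub + 1, 0)
        aucs = inside.sum(axis=1) / (top_t * len(in_db))
        sd = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0
        mean = float(np.mean(aucs))
        if sd == 0:
            warnings.warn(
                f"AUC spread across motifs is zero for {tf!r}; NES undefined",
                stacklevel=2,
            )
        annotated = set(db.motifs_for_tf(tf))
        for i, motif in enumerate(db.motif_ids):
            if motif not in annotated:
                continue
            nes = (float(aucs[i]) - mean) / sd if sd > 0 else 0.0
            leading = frozenset(
                t for t, c in zip(in_db, cols) if db.ranks[i, c] <= top_t
            )
            results.append(
                MotifEnrichment(
                    tf=tf, motif_id=motif, auc=float(aucs[i]), nes=nes,
                    enriched=bool(sd > 0 and nes >= nes_cut),
                    leading_edge=leading,
                )
            )
    return results


def prune_to_grn(
    candidates: Sequence[CandidateEdge],
    enrichments: Sequence[MotifEnrichment],
    keep_unannotated: bool = False,
) -> RegulatoryNetwork:
    """Keep candidate edges whose target sits in the leading edge of an
    enriched motif annotated to the TF; attach the best-NES supporting
    motif. TFs without any annotated motif lose all their edges (flagged),
    unless ``keep_unannotated`` passes them through with empty evidence."""
    by_tf: dict[str, list[MotifEnrichment]] = {}
    for e in enrichments:
        by_tf.setdefault(e.tf, []).append(e)

    rows = []
    unannotated: set[str] = set()
    for c in candidates:
        motifs = by_tf.get(c.tf, [])
        if not motifs:
            unannotated.add(c.tf)
            if keep_unannotated:
                rows.append({"tf": c.tf, "target": c.target,
                             "importance": c.importance, "motif_id": "",
                             "auc": float("nan"), "nes": float("nan"),
                             "unannotated": True})
            continue
        support = [m for m in motifs if m.enriched and c.target in m.leading_edge]
        if not support:
            continue
        best = max(support, key=lambda m: m.nes)
        rows.append({"tf": c.tf, "target": c.target, "importance": c.importance,
                     "motif_id": best.motif_id, "auc": best.auc, "nes": best.nes,
                     "unannotated": False})
    edges = pd.DataFrame(
        rows,
        columns=["tf", "target", "importance", "motif_id", "auc", "nes",
                 "unannotated"],
    )
    if unannotated:
        logger.warning("TFs with no motif annotation: %s", sorted(unannotated))
    return RegulatoryNetwork(edges=edges, unannotated_tfs=sorted(unannotated))
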