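"""Synthetic single-cell fixtures with known ground truth.

The generator emulates the structure the pipeline is built to recover: a
negative-binomial count matrix with planted co-expression modules driven by
latent per-cell module activities, sub-population ("blob") structure inside
each cell group for the representative-cell step, a motif ranking database
whose true motifs concentrate each driver TF's regulon near the top, and a
toy drug-target table. Everything is deterministic under a seed, so every
pipeline stage can be verified against the planted truth offline.

Model: each cell belongs to a group and, within it, a blob; module m has a
per-(group, blob) mean shift and each cell draws an activity
z_m ~ Normal(shift, factor_sd). A module gene's log mean is its baseline
plus loading * z_m (the designated driver TF uses loading 1). Counts are
negative binomial via the gamma-Poisson mixture with a fixed dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import DrugTargetTable, ExpressionMatrix, MotifRankingDB


@dataclass
class GroundTruth:
    module_of: dict[str, int]  # gene -> planted module, 0 = background
    driver_tf: dict[int, str]  # module -> its driver TF symbol
    regulon: dict[str, set[str]]  # TF -> planted target set
    blob_of: dict[str, str]  # cell -> planted sub-population
    motif_truth: dict[str, str] = field(default_factory=dict)  # motif -> TF

    def module_labels(self, genes: list[str]) -> np.ndarray:
        return np.array([self.module_of.get(g, 0) for g in genes], dtype=int)


def make_ground_truth(
    n_genes: int = 1000, n_modules: int = 5, module_size: int = 60
) -> tuple[list[str], GroundTruth, np.ndarray, np.ndarray]:
    """Gene symbols and planted truth for the default module layout.

    Returns (genes, truth, per-gene module index array, per-gene loading
    multiplier with drivers at 1). Used by :func:`simulate_counts` and
    usable on its own when only the regulon structure is needed (e.g. for
    motif-database simulation).
    """
    if n_modules * module_size > n_genes:
        raise ValueError("n_modules * module_size exceeds n_genes")
    genes: list[str] = []
    module_of: dict[str, int] = {}
    driver_tf: dict[int, str] = {}
    regulon: dict[str, set[str]] = {}
    gene_module = np.zeros(n_genes, dtype=int)
    is_driver = np.zeros(n_genes, dtype=bool)
    gi = 0
    for m in range(1, n_modules + 1):
        tf = f"TF{m}"
        genes.append(tf)
        module_of[tf] = m
        driver_tf[m] = tf
        gene_module[gi] = m
        is_driver[gi] = True
        gi += 1
        members = []
        for j in range(module_size - 1):
            name = f"M{m}G{j:03d}"
            genes.append(name)
            module_of[name] = m
            gene_module[gi] = m
            gi += 1
            members.append(name)
        regulon[tf] = set(members)
    for j in range(n_genes - gi):
        name = f"B{j:04d}"
        genes.append(name)
        module_of[name] = 0
    truth = GroundTruth(module_of=module_of, driver_tf=driver_tf,
                        regulon=regulon, blob_of={})
    return genes, truth, gene_module, is_driver


def simulate_counts(
    n_groups: int = 2,
    cells_per_group: int = 300,
    blobs_per_group: int = 5,
    n_genes: int = 1000,
    n_modules: int = 5,
    module_size: int = 60,
    factor_sd: float = 1.0,
    loading: float = 0.8,
    nb_dispersion: float = 0.5,
    base_mean_log_range: tuple[float, float] = (0.5, 3.0),
    blob_shift_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Negative-binomial counts with planted co-expression modules.

    Returns the (cells x genes) count matrix with group/blob metadata and
    the planted truth. Gene symbols: the driver TF of module m is ``TFm``,
    its members ``MmGjjj``, background genes ``Bjjjj``.
    """
    if n_groups < 1 or cells_per_group < 1 or blobs_per_group < 1:
        raise ValueError("group/cell/blob counts must be positive")
    rng = np.random.default_rng(seed)

    genes, truth, gene_module, is_driver = make_ground_truth(
        n_genes, n_modules, module_size)
    loadings = np.where(is_driver, 1.0, loading) * (gene_module > 0)

    base_log_mean = rng.uniform(*base_mean_log_range, size=n_genes)

    n_cells = n_groups * cells_per_group
    cell_ids, group_col, blob_col = [], [], []
    blob_of: dict[str, str] = {}
    # per (group, blob, module) mean shift of the latent activity
    shifts = rng.normal(0.0, blob_shift_sd, size=(n_groups, blobs_per_group, n_modules))

    counts = np.zeros((n_cells, n_genes))
    row = 0
    for g in range(n_groups):
        group = f"group{g + 1}"
        blob_assign = rng.integers(0, blobs_per_group, size=cells_per_group)
        for c in range(cells_per_group):
            cid = f"{group}_c{c:04d}"
            b = int(blob_assign[c])
            cell_ids.append(cid)
            group_col.append(group)
            blob_col.append(f"{group}_blob{b}")
            blob_of[cid] = f"{group}_blob{b}"
            z = rng.normal(shifts[g, b], factor_sd)  # one activity per module
            log_mean = base_log_mean.copy()
            active = gene_module > 0
            log_mean[active] += loadings[active] * z[gene_module[active] - 1]
            mean = np.exp(log_mean)
            lam = rng.gamma(shape=1.0 / nb_dispersion, scale=mean * nb_dispersion)
            counts[row] = rng.poisson(lam)
            row += 1

    meta = pd.DataFrame(
        {"group": group_col, "blob": blob_col},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    expr = ExpressionMatrix(counts, genes, cell_ids, meta)
    truth.blob_of = blob_of
    return expr, truth


def simulate_motif_db(
    truth: GroundTruth,
    gene_universe: list[str],
    n_motifs: int = 50,
    signal_frac: float = 0.9,
    top_frac: float = 0.05,
    decoys_per_tf: int = 2,
    seed: int = 0,
) -> MotifRankingDB:
    """Motif ranking database consistent with the planted regulons.

    Each driver TF gets one true motif that places a ``signal_frac``
    fraction of its regulon uniformly within the top ``top_frac`` ranks
    (everything else uniform), plus ``decoys_per_tf`` annotated decoy
    motifs with fully random rankings. Remaining motifs are unannotated
    random permutations.
    """
    if not truth.regulon:
        raise ValueError("ground truth has no regulons")
    rng = np.random.default_rng(seed)
    g_count = len(gene_universe)
    top_t = int(np.ceil(top_frac * g_count))
    gene_pos = {g: i for i, g in enumerate(gene_universe)}

    motif_ids: list[str] = []
    rows: list[np.ndarray] = []
    motif2tf: set[tuple[str, str]] = set()
    motif_truth: dict[str, str] = {}

    def random_row() -> np.ndarray:
        return rng.permutation(g_count) + 1

    for m, tf in sorted(truth.driver_tf.items()):
        reg = sorted(truth.regulon[tf])
        # the top region only has top_t slots; cap the placed signal there
        n_signal = min(int(np.ceil(signal_frac * len(reg))), top_t)
        signal = list(rng.choice(reg, size=n_signal, replace=False)) if n_signal else []
        ranks = np.zeros(g_count, dtype=int)
        top_positions = rng.choice(np.arange(1, top_t + 1), size=len(signal),
                                   replace=False)
        for gname, r in zip(signal, top_positions):
            ranks[gene_pos[gname]] = r
        remaining_ranks = np.setdiff1d(np.arange(1, g_count + 1), top_positions)
        rest_idx = np.array([i for i in range(g_count) if ranks[i] == 0])
        ranks[rest_idx] = rng.permutation(remaining_ranks)
        motif_id = f"motif_true_{tf}"
        motif_ids.append(motif_id)
        rows.append(ranks)
        motif2tf.add((motif_id, tf))
        motif_truth[motif_id] = tf
        for d in range(decoys_per_tf):
            decoy_id = f"motif_decoy_{tf}_{d}"
            motif_ids.append(decoy_id)
            rows.append(random_row())
            motif2tf.add((decoy_id, tf))

    while len(motif_ids) < n_motifs:
        motif_ids.append(f"motif_bg_{len(motif_ids):03d}")
        rows.append(random_row())

    db = MotifRankingDB(
        motif_ids=motif_ids,
        gene_ids=list(gene_universe),
        ranks=np.vstack(rows),
        motif2tf=motif2tf,
    )
    truth.motif_truth = motif_truth
    return db


def simulate_drug_table(
    genes: list[str],
    n_drugs: int = 30,
    targets_per_drug: tuple[int, int] = (1, 3),
    seed: int = 0,
) -> DrugTargetTable:
    """Toy drug-target table: each drug hits 1-3 uniformly sampled genes."""
    if n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_drugs):
        drug_id = f"DR{d:04d}"
        n_t = int(rng.integers(targets_per_drug[0], targets_per_drug[1] + 1))
        targets = rng.choice(genes, size=min(n_t, len(genes)), replace=False)
        for t in targets:
            rows.append({"drug_id": drug_id, "drug_name": f"drug-{d:04d}",
                         "gene_symbol": str(t), "action": "", "source": "synthetic"})
    df = pd.DataFrame(rows, columns=list(DrugTargetTable.REQUIRED))
    return DrugTargetTable(df, provenance=f"synthetic drug table (seed={seed})")


def write_scenario(out_dir: str | Path, seed: int = 1, **kwargs) -> dict[str, Path]:
    """Write a complete fixture set (counts, metadata, TF list, motif DB,
    drug table) in the plain-text pipeline formats; returns the paths."""
    from .io_formats import write_expression_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, truth = simulate_counts(seed=seed, **kwargs)
    db = simulate_motif_db(truth, expr.gene_ids, seed=seed + 1)
    drugs = simulate_drug_table(expr.gene_ids, seed=seed + 2)

    paths = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "tf_list": out / "tfs.txt",
        "motif_ranks": out / "motif_ranks.tsv",
        "motif2tf": out / "motif2tf.tsv",
        "drug_table": out / "drugs.tsv",
        "truth_modules": out / "truth_modules.tsv",
    }
    write_expression_tsv(expr, paths["counts"])
    expr.metadata.to_csv(paths["metadata"], sep="\t")
    paths["tf_list"].write_text(
        "\n".join(truth.driver_tf[m] for m in sorted(truth.driver_tf)) + "\n"
    )
    pd.DataFrame(db.ranks, index=pd.Index(db.motif_ids, name="motif_id"),
                 columns=db.gene_ids).to_csv(paths["motif_ranks"], sep="\t")
    pd.DataFrame(sorted(db.motif2tf), columns=["motif_id", "tf_symbol"]).to_csv(
        paths["motif2tf"], sep="\t", index=False
    )
    with open(paths["drug_table"], "w", encoding="utf-8") as fh:
        fh.write(f"# {drugs.provenance}\n")
        drugs.records.to_csv(fh, sep="\t", index=False)
    pd.DataFrame(
        {"gene": expr.gene_ids, "module": truth.module_labels(expr.gene_ids)}
    ).to_csv(paths["truth_modules"], sep="\t", index=False)
    return paths


def linear_regulation_fixture(
    n_samples: int = 200,
    n_decoy_tfs: int = 9,
    n_targets: int = 10,
    effect: float = 3.0,
    noise_sd_frac: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, str, list[str], list[str]]:
    """Linear-regulation benchmark: one driver TF whose targets are
    ``effect * TF + noise``; decoy TFs are independent noise.

    Returns (expression frame, driver TF name, all TF names, target names).
    """
    rng = np.random.default_rng(seed)
    driver = "TF_driver"
    tfs = [driver] + [f"TF_decoy{i}" for i in range(n_decoy_tfs)]
    data = {t: rng.normal(0, 1, n_samples) for t in tfs}
    targets = []
    sd = noise_sd_frac * np.std(data[driver])
    for j in range(n_targets):
        name = f"TG{j:02d}"
        data[name] = effect * data[driver] + rng.normal(0, sd, n_samples)
        targets.append(name)
    frame = pd.DataFrame(data, index=[f"s{i}" for i in range(n_samples)])
    return frame, driver, tfs, targets
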