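"""Weighted gene co-expression networks, modules, hubs, and trait links.

The chain is the weighted-network workflow familiar from bulk co-expression
analysis, run on representative cells: a gene-gene correlation matrix
(biweight midcorrelation by default, which down-weights outliers), raised to
a soft-threshold power beta to form a signed adjacency, converted to the
topological overlap matrix (TOM), and clustered with average linkage on
1 - TOM. Modules are summarized by eigengenes (first principal component of
the module's standardized expression), correlated against per-cell traits,
and screened for hub genes in the intersection of the top intramodular
connectivity (kIM) and module membership (kME) deciles.

Module detection here uses a static branch cut at a fraction of the tree
height plus a minimum module size and eigengene-based merging; this is a
deliberately deterministic simplification of dynamic hybrid tree cutting.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CorrelationMethod = Literal["pearson", "spearman", "bicor"]
NetworkType = Literal["signed", "signed_hybrid", "unsigned"]

GREY = 0  # module label for unassigned genes


@dataclass
class CorrelationMatrix:
    genes: list[str]
    values: np.ndarray
    method: CorrelationMethod

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix shape mismatch")


@dataclass
class AdjacencyMatrix:
    genes: list[str]
    values: np.ndarray
    network_type: NetworkType
    beta: float


@dataclass
class TOMMatrix:
    genes: list[str]
    values: np.ndarray

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.values


@dataclass
class ScaleFreeFit:
    r2: float  # R^2 signed by -sign(slope): positive when scale-free-like
    slope: float
    n_bins: int


@dataclass
class SoftThresholdResult:
    beta: int
    table: pd.DataFrame  # power, r2, slope, mean_k, median_k, max_k
    passed: bool  # False when no power reached r2_cut


@dataclass
class ModuleSet:
    genes: list[str]
    labels: np.ndarray  # int per gene, 0 = grey/unassigned
    eigengenes: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    var_explained: pd.Series = field(default=None)  # type: ignore[assignment]
    kim: pd.Series = field(default=None)  # type: ignore[assignment]
    kme: pd.Series = field(default=None)  # type: ignore[assignment]
    hubs: dict[int, list[str]] = field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in np.unique(self.labels) if m != GREY)

    def module_genes(self, module: int) -> list[str]:
        return [g for g, lab in zip(self.genes, self.labels) if lab == module]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene": self.genes, "module": self.labels.astype(int)})
        if self.kim is not None:
            df["kIM"] = self.kim.reindex(self.genes).to_numpy()
        if self.kme is not None:
            df["kME"] = self.kme.reindex(self.genes).to_numpy()
        if self.hubs:
            hubset = {g for gs in self.hubs.values() for g in gs}
            df["is_hub"] = df["gene"].isin(hubset)
        return df


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def _bicor_transform(x: np.ndarray) -> np.ndarray:
    """Robust transform for one gene vector; None-like zeros signal mad == 0."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.array([])  # sentinel: caller falls back to Pearson
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w


def bicor_vector(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two vectors (direct formula evaluation)."""
    xt = _bicor_transform(np.asarray(x, dtype=float))
    yt = _bicor_transform(np.asarray(y, dtype=float))
    if xt.size == 0 or yt.size == 0:
        raise ValueError("mad == 0: bicor undefined, use Pearson")
    denom = math.sqrt(float(xt @ xt) * float(yt @ yt))
    return float(xt @ yt) / denom


def correlation_matrix(
    values: np.ndarray | pd.DataFrame,
    genes: Sequence[str] | None = None,
    method: CorrelationMethod = "bicor",
) -> CorrelationMatrix:
    """Pairwise gene-gene correlation over samples (rows).

    ``bicor`` uses the biweight midcorrelation: with u_i = (x_i - med) /
    (9 mad) and weights w_i = (1 - u_i^2)^2 for |u_i| < 1 (else 0), each
    vector is replaced by (x_i - med) w_i and the correlation is the cosine
    of the transformed vectors. Genes whose mad is zero fall back to a
    Pearson-standardized vector for their pairs (logged). Zero-variance
    genes under Pearson correlate as 0 with a warning.
    """
    if isinstance(values, pd.DataFrame):
        genes = [str(c) for c in values.columns]
        values = values.to_numpy(dtype=float)
    values = np.asarray(values, dtype=float)
    n_samples, n_genes = values.shape
    if genes is None:
        genes = [f"g{i}" for i in range(n_genes)]
    if n_samples < 3:
        raise ValueError(f"need >= 3 samples for correlation, got {n_samples}")

    if method == "spearman":
        work = np.apply_along_axis(rankdata, 0, values)
    else:
        work = values

    cols = np.empty_like(work, dtype=float)
    zero_var: list[str] = []
    mad_fallback: list[str] = []
    for j in range(n_genes):
        x = work[:, j]
        if method == "bicor":
            xt = _bicor_transform(x)
            if xt.size == 0:
                mad_fallback.append(genes[j])
                xt = x - x.mean()
        else:
            xt = x - x.mean()
        norm = np.linalg.norm(xt)
        if norm == 0:
            zero_var.append(genes[j])
            cols[:, j] = 0.0
        else:
            cols[:, j] = xt / norm

    if mad_fallback:
        logger.info("bicor: %d genes with mad=0 fell back to Pearson: %s",
                    len(mad_fallback), mad_fallback[:5])
    if zero_var:
        warnings.warn(
            f"{len(zero_var)} zero-variance genes; their correlations are set to 0",
            stacklevel=2,
        )

    cor = cols.T @ cols
    np.clip(cor, -1.0, 1.0, out=cor)
    cor = (cor + cor.T) / 2.0
    np.fill_diagonal(cor, 1.0)
    for j, g in enumerate(genes):
        if g in zero_var:
            cor[j, :] = 0.0
            cor[:, j] = 0.0
            cor[j, j] = 1.0
    return CorrelationMatrix(list(genes), cor, method)


# ---------------------------------------------------------------------------
# adjacency / TOM / scale-free fit
# ---------------------------------------------------------------------------

def adjacency(
    cor: CorrelationMatrix, network_type: NetworkType = "signed", beta: float = 6
) -> AdjacencyMatrix:
    """Soft-threshold the correlation matrix into edge weights in [0, 1].

    signed: a = ((1 + cor) / 2)^beta — anti-correlated genes get weight
    near 0, preserving the sign information. signed_hybrid: positive
    correlations raised to beta, negative set to 0. unsigned: |cor|^beta.
    """
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    c = cor.values
    if network_type == "signed":
        a = ((1.0 + c) / 2.0) ** beta
    elif network_type == "signed_hybrid":
        a = np.where(c > 0, c, 0.0) ** beta
    elif network_type == "unsigned":
        a = np.abs(c) ** beta
    else:
        raise ValueError(f"unknown network type {network_type!r}")
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(cor.genes, a, network_type, float(beta))


def connectivity(adj: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij (self excluded)."""
    a = adj.values if isinstance(adj, AdjacencyMatrix) else np.asarray(adj, float)
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


def scale_free_fit(adj: AdjacencyMatrix | np.ndarray, n_bins: int = 10) -> ScaleFreeFit:
    """Scale-free topology fit index of the connectivity distribution.

    Connectivities are binned into ``n_bins`` equal-width bins; the discrete
    frequency p(k) per non-empty bin is regressed (OLS) as log10 p(k) on
    log10(mean k in bin). The returned r2 is R^2 times -sign(slope), so a
    scale-free-like decreasing distribution gives a positive index.
    """
    if isinstance(adj, np.ndarray) and adj.ndim == 1:
        k = np.asarray(adj, dtype=float)  # a precomputed degree sequence
    else:
        k = connectivity(adj)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    if edges[0] == edges[-1]:
        raise ValueError("all connectivities equal: degenerate single-bin input")
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_p, log_k = [], []
    for b in range(n_bins):
        sel = idx == b
        cnt = int(sel.sum())
        if cnt == 0:
            continue
        mean_k = float(k[sel].mean())
        if mean_k <= 0:
            continue
        log_p.append(math.log10(cnt / len(k)))
        log_k.append(math.log10(mean_k))
    if len(log_k) < 3:
        raise ValueError(f"only {len(log_k)} usable bins; need >= 3 for the fit")
    x = np.asarray(log_k)
    y = np.asarray(log_p)
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return ScaleFreeFit(r2=r2 * -np.sign(slope), slope=float(slope), n_bins=len(log_k))


def pick_soft_threshold(
    cor: CorrelationMatrix,
    network_type: NetworkType = "signed",
    powers: Sequence[int] = tuple(range(1, 21)),
    r2_cut: float = 0.85,
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Choose the smallest power whose scale-free fit reaches ``r2_cut``.

    If no power qualifies, the power with the best fit is returned and the
    ``passed`` flag is False. The per-power table also reports mean, median
    and max connectivity, which shrink monotonically in the power.
    """
    if not powers:
        raise ValueError("powers must be non-empty")
    rows = []
    for p in powers:
        adj = adjacency(cor, network_type, p)
        k = connectivity(adj)
        try:
            fit = scale_free_fit(adj, n_bins=n_bins)
            r2, slope = fit.r2, fit.slope
        except ValueError:
            r2, slope = float("nan"), float("nan")
        rows.append(
            {"power": int(p), "r2": r2, "slope": slope,
             "mean_k": float(k.mean()), "median_k": float(np.median(k)),
             "max_k": float(k.max())}
        )
    table = pd.DataFrame(rows)
    ok = table[table["r2"] >= r2_cut]
    if len(ok):
        beta = int(ok["power"].iloc[0])
        passed = True
    else:
        valid = table.dropna(subset=["r2"])
        if len(valid) == 0:
            beta = int(table["power"].iloc[0])
        else:
            beta = int(valid.loc[valid["r2"].idxmax(), "power"])
        passed = False
        logger.warning("no power reached r2 >= %.2f; using best power %d", r2_cut, beta)
    return SoftThresholdResult(beta=beta, table=table, passed=passed)


def tom_similarity(adj: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap: direct adjacency plus shared-neighbor weight.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    for i != j, and TOM_ii = 1. Values stay in [0, 1] for adjacency in [0, 1].
    """
    a = adj.values.copy()
    np.fill_diagonal(a, 0.0)
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a  # (shared)_ij = sum_u a_iu a_uj, includes u = i, j terms = 0
    num = shared + a
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return TOMMatrix(adj.genes, tom)


# ---------------------------------------------------------------------------
# eigengenes and modules
# ---------------------------------------------------------------------------

def _zscore(mat: np.ndarray) -> np.ndarray:
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    return (mat - mu) / sd


def _eigengene(mat: np.ndarray) -> tuple[np.ndarray, float]:
    """First PC score over samples of the z-scored module matrix, unit norm,
    oriented so mean correlation with member genes is >= 0; plus the
    fraction of variance it explains."""
    z = _zscore(mat)
    if z.shape[1] == 1:
        v = z[:, 0]
        norm = np.linalg.norm(v)
        e = v / norm if norm > 0 else v
        return e, 1.0
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    e = u[:, 0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    cors = np.array([_safe_pearson(e, z[:, j]) for j in range(z.shape[1])])
    if np.nanmean(cors) < 0:
        e = -e
    return e, var_explained


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    d = np.linalg.norm(xc) * np.linalg.norm(yc)
    if d == 0:
        return 0.0
    return float(xc @ yc / d)


def module_eigengenes(
    expr: np.ndarray | pd.DataFrame,
    genes: Sequence[str],
    labels: np.ndarray,
    sample_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengene (first PC summary profile) per non-grey module.

    Returns (eigengenes: samples x modules, var_explained per module).
    Single-gene modules use the gene's z-score as their profile (logged).
    """
    if isinstance(expr, pd.DataFrame):
        sample_ids = [str(i) for i in expr.index]
        expr = expr.to_numpy(dtype=float)
    labels = np.asarray(labels)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(expr.shape[0])]
    gene_index = {g: i for i, g in enumerate(genes)}
    eig: dict[str, np.ndarray] = {}
    var_exp: dict[str, float] = {}
    for m in sorted(int(x) for x in np.unique(labels) if x != GREY):
        cols = [gene_index[g] for g, lab in zip(genes, labels) if lab == m]
        if len(cols) == 1:
            logger.info("module %d has a single gene; eigengene is its z-score", m)
        e, ve = _eigengene(expr[:, cols])
        eig[f"M{m}"] = e
        var_exp[f"M{m}"] = ve
    eig_df = pd.DataFrame(eig, index=pd.Index(sample_ids, name="cell_id"))
    return eig_df, pd.Series(var_exp, name="var_explained")


def _merge_close_modules(
    expr: np.ndarray,
    genes: Sequence[str],
    labels: np.ndarray,
    merge_cut: float,
) -> np.ndarray:
    """Iteratively merge module pairs whose eigengenes correlate >= 1 - merge_cut,
    closest pair first."""
    labels = labels.copy()
    while True:
        mods = sorted(int(m) for m in np.unique(labels) if m != GREY)
        if len(mods) < 2:
            return labels
        eig_df, _ = module_eigengenes(expr, genes, labels)
        best: tuple[float, int, int] | None = None
        for i, m1 in enumerate(mods):
            for m2 in mods[i + 1:]:
                c = _safe_pearson(
                    eig_df[f"M{m1}"].to_numpy(), eig_df[f"M{m2}"].to_numpy()
                )
                if c >= 1.0 - merge_cut and (best is None or c > best[0]):
                    best = (c, m1, m2)
        if best is None:
            return labels
        _, m1, m2 = best
        labels[labels == m2] = m1


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..M by decreasing size (ties by old label)."""
    out = np.zeros_like(labels)
    mods = [int(m) for m in np.unique(labels) if m != GREY]
    sizes = {m: int((labels == m).sum()) for m in mods}
    for new, m in enumerate(sorted(mods, key=lambda m: (-sizes[m], m)), start=1):
        out[labels == m] = new
    return out


def detect_modules(
    tom: TOMMatrix,
    expr: np.ndarray | pd.DataFrame,
    min_module_size: int = 30,
    cut_height_frac: float = 0.995,
    merge_cut: float = 0.25,
) -> ModuleSet:
    """Cluster genes into co-expression modules from the TOM.

    Average-linkage hierarchical clustering on 1 - TOM, cut statically at
    ``cut_height_frac`` of the tree height; branches below
    ``min_module_size`` genes fall into the grey (unassigned, label 0)
    module; modules whose eigengenes correlate at least 1 - ``merge_cut``
    are merged, closest pair first; surviving modules are renumbered 1..M by
    decreasing size.
    """
    if isinstance(expr, pd.DataFrame):
        expr_vals = expr.to_numpy(dtype=float)
        sample_ids = [str(i) for i in expr.index]
    else:
        expr_vals = np.asarray(expr, dtype=float)
        sample_ids = None
    genes = tom.genes
    diss = tom.dissimilarity
    condensed = squareform((diss + diss.T) / 2.0, checks=False)
    tree = linkage(condensed, method="average")
    max_h = tree[:, 2].max()
    raw = fcluster(tree, t=cut_height_frac * max_h, criterion="distance")

    labels = np.zeros(len(genes), dtype=int)
    next_id = 1
    for c in np.unique(raw):
        members = raw == c
        if members.sum() >= min_module_size:
            labels[members] = next_id
            next_id += 1
    if (labels == GREY).all():
        warnings.warn("all genes unassigned (grey); no module passed the size cut",
                      stacklevel=2)
        return ModuleSet(genes=list(genes), labels=labels)

    labels = _merge_close_modules(expr_vals, genes, labels, merge_cut)
    labels = _renumber_by_size(labels)
    eig_df, var_exp = module_eigengenes(expr_vals, genes, labels, sample_ids)
    return ModuleSet(genes=list(genes), labels=labels, eigengenes=eig_df,
                     var_explained=var_exp)


# ---------------------------------------------------------------------------
# module statistics
# ---------------------------------------------------------------------------

def intramodular_connectivity(adj: AdjacencyMatrix, labels: np.ndarray) -> pd.Series:
    """kIM_i: summed adjacency of gene i to same-module partners (grey -> 0)."""
    labels = np.asarray(labels)
    a = adj.values.copy()
    np.fill_diagonal(a, 0.0)
    kim = np.zeros(len(adj.genes))
    for m in np.unique(labels):
        if m == GREY:
            continue
        sel = labels == m
        kim[sel] = a[np.ix_(sel, sel)].sum(axis=1)
    return pd.Series(kim, index=pd.Index(adj.genes, name="gene"), name="kIM")


def module_membership(
    expr: np.ndarray | pd.DataFrame,
    genes: Sequence[str],
    labels: np.ndarray,
    eigengenes: pd.DataFrame,
    method: CorrelationMethod = "bicor",
) -> pd.Series:
    """kME_i: correlation of gene i with its own module's eigengene.

    Uses the same correlation flavor as the network; grey genes get 0.
    """
    if isinstance(expr, pd.DataFrame):
        expr = expr.to_numpy(dtype=float)
    labels = np.asarray(labels)
    kme = np.zeros(len(genes))
    for j, (g, m) in enumerate(zip(genes, labels)):
        if m == GREY:
            continue
        e = eigengenes[f"M{int(m)}"].to_numpy()
        x = expr[:, j]
        if method == "bicor":
            try:
                kme[j] = bicor_vector(x, e)
            except ValueError:
                kme[j] = _safe_pearson(x, e)
        elif method == "spearman":
            kme[j] = _safe_pearson(rankdata(x), rankdata(e))
        else:
            kme[j] = _safe_pearson(x, e)
    return pd.Series(kme, index=pd.Index(list(genes), name="gene"), name="kME")


def detect_hubs(
    module_genes: Sequence[str],
    kim: pd.Series,
    kme: pd.Series,
    top_frac: float = 0.10,
) -> list[str]:
    """Hub genes: intersection of the top ``top_frac`` by kIM and by kME.

    The top list size is ceil(top_frac * module size); ties break
    lexicographically by gene symbol so results are deterministic.
    """
    m = len(module_genes)
    if m < 2:
        warnings.warn("module has < 2 genes; no hubs", stacklevel=2)
        return []
    n_top = math.ceil(top_frac * m)

    def top_by(score: pd.Series) -> set[str]:
        ordered = sorted(module_genes, key=lambda g: (-float(score[g]), g))
        return set(ordered[:n_top])

    return sorted(top_by(kim) & top_by(kme))


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    metadata: pd.DataFrame,
    method: Literal["spearman", "pearson"] = "spearman",
) -> pd.DataFrame:
    """Correlate module eigengenes with per-cell traits.

    Categorical metadata columns are expanded to one-hot indicators;
    numeric columns are used as-is. Returns a long table (module, trait,
    rho, p, p_adj) with Benjamini-Hochberg adjustment across the whole
    matrix. Constant traits yield rho = 0 with a ``constant`` flag.
    """
    meta = metadata.loc[eigengenes.index]
    traits: dict[str, np.ndarray] = {}
    for col in meta.columns:
        s = meta[col]
        if pd.api.types.is_numeric_dtype(s):
            traits[col] = s.to_numpy(dtype=float)
        else:
            for val in sorted(s.astype(str).unique()):
                traits[f"{col}={val}"] = (s.astype(str) == val).to_numpy(dtype=float)
    rows = []
    for mod in eigengenes.columns:
        e = eigengenes[mod].to_numpy()
        for tname, tvec in traits.items():
            flag = ""
            if np.all(tvec == tvec[0]) or np.all(e == e[0]):
                rho, p = 0.0, 1.0
                flag = "constant"
            elif method == "spearman":
                rho, p = spearmanr(e, tvec)
            else:
                from scipy.stats import pearsonr
                rho, p = pearsonr(e, tvec)
            rows.append({"module": mod, "trait": tname, "rho": float(rho),
                         "p": float(p), "flag": flag})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["p_adj"] = np.maximum(out["p_adj"], out["p"])  # guard fp rounding
    return out[["module", "trait", "rho", "p", "p_adj", "flag"]]


def extract_submodule(
    cor: CorrelationMatrix,
    module_genes: Sequence[str],
    threshold: float,
    signed: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """Strong-edge sub-network of a module at a correlation threshold.

    Keeps within-module edges with correlation >= threshold (the raw value
    for signed networks, |cor| for unsigned); returns the genes incident to
    at least one kept edge and the edge list.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    idx = {g: i for i, g in enumerate(cor.genes)}
    missing = [g for g in module_genes if g not in idx]
    if missing:
        raise KeyError(f"genes absent from correlation matrix: {missing[:5]}")
    rows = []
    kept: set[str] = set()
    mg = list(module_genes)
    for i, g1 in enumerate(mg):
        for g2 in mg[i + 1:]:
            c = float(cor.values[idx[g1], idx[g2]])
            stat = c if signed else abs(c)
            if stat >= threshold:
                rows.append({"gene1": g1, "gene2": g2, "correlation": c})
                kept.update((g1, g2))
    edges = pd.DataFrame(rows, columns=["gene1", "gene2", "correlation"])
    return sorted(kept), edges
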