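"""Signed weighted co-expression network and module detection.

Pipeline: pairwise Pearson correlation over samples -> signed adjacency
``adj = (0.5*(1+cor))^beta`` with the softpower beta chosen by a scale-free
topology fit -> topological overlap matrix (TOM) -> average-linkage
hierarchical clustering on 1-TOM with a static height cut and a minimum
module size -> eigengene-based merging of similar modules -> export of the
highly co-expressed within-module edges (|cor| above a threshold).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .expression_preprocess import ExprMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionNetwork",
    "SoftThresholdFit",
    "ModulePartition",
    "BACKGROUND_LABEL",
    "correlation_matrix",
    "signed_adjacency",
    "scale_free_fit",
    "pick_soft_threshold",
    "tom_matrix",
    "cluster_and_cut",
    "module_eigengene",
    "merge_modules",
    "export_edges",
]

BACKGROUND_LABEL = "background"


@dataclass
class SoftThresholdFit:
    """Scale-free fit per candidate softpower and the chosen value."""

    table: pd.DataFrame  # columns: beta, signed_r2, mean_connectivity
    chosen_beta: int
    target_r2: float

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"SoftThresholdFit(chosen_beta={self.chosen_beta}, "
                f"target_r2={self.target_r2})")


@dataclass
class ModulePartition:
    """Gene -> module assignment with eigengenes and merge history."""

    module_of_gene: pd.Series
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # samples x modules
    variance_explained: dict[str, float] = field(default_factory=dict)
    merge_history: list[tuple[str, str]] = field(default_factory=list)

    @property
    def modules(self) -> list[str]:
        return [m for m in self.module_of_gene.unique() if m != BACKGROUND_LABEL]

    @property
    def module_sizes(self) -> pd.Series:
        counts = self.module_of_gene.value_counts()
        return counts[counts.index != BACKGROUND_LABEL]

    def genes_in(self, module: str) -> list[str]:
        return list(self.module_of_gene.index[self.module_of_gene == module])


@dataclass
class CoexpressionNetwork:
    """Correlation, adjacency and TOM over a fixed gene index."""

    gene_ids: list[str]
    cor: np.ndarray
    beta: int
    adj: np.ndarray
    tom: np.ndarray


def correlation_matrix(expr: ExprMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of genes across samples.

    Zero-variance genes get correlation 0 to every partner (with a warning)
    rather than NaN, so the downstream adjacency stays finite.
    """
    values = expr.values if isinstance(expr, ExprMatrix) else expr
    if values.shape[1] < 3:
        raise ValueError("correlation needs at least 3 samples")
    x = values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s); their correlations are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(x)
    cor[np.isnan(cor)] = 0.0
    np.fill_diagonal(cor, 1.0)
    cor = np.clip(cor, -1.0, 1.0)
    return pd.DataFrame(cor, index=values.index, columns=values.index)


def signed_adjacency(cor: pd.DataFrame | np.ndarray | float, beta: int) -> np.ndarray:
    """Signed adjacency ``((1 + cor) / 2) ** beta``; maps cor -1 -> 0, +1 -> 1."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    c = np.asarray(cor, dtype=float)
    if np.any(c < -1 - 1e-9) or np.any(c > 1 + 1e-9):
        raise ValueError("correlations must lie in [-1, 1]")
    return (0.5 * (1.0 + c)) ** beta


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the scale-free topology fit of a connectivity vector.

    Connectivity is binned into ``n_bins`` equal-width bins; log10 frequency
    is regressed on log10 mean connectivity over the nonempty bins and the
    returned statistic is ``-sign(slope) * R^2``.
    """
    k = np.asarray(connectivity, dtype=float)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq, mean_k = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size and members.mean() > 0:
            freq.append(members.size / k.size)
            mean_k.append(members.mean())
    if len(freq) < 2:
        raise ValueError("degenerate connectivity distribution: fewer than 2 "
                         "nonempty bins")
    x = np.log10(np.asarray(mean_k))
    y = np.log10(np.asarray(freq))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def pick_soft_threshold(
    expr: ExprMatrix | pd.DataFrame,
    betas: list[int] | range = range(1, 31),
    target_r2: float = 0.85,
) -> SoftThresholdFit:
    """Choose the smallest softpower whose scale-free fit reaches the target.

    If no candidate reaches ``target_r2`` the beta maximising the signed R^2
    is chosen with a warning.
    """
    betas = list(betas)
    if not betas:
        raise ValueError("candidate beta list is empty")
    cor = correlation_matrix(expr).to_numpy()
    rows = []
    for beta in betas:
        adj = signed_adjacency(cor, beta)
        k = adj.sum(axis=1) - np.diag(adj)
        rows.append({
            "beta": beta,
            "signed_r2": scale_free_fit(k),
            "mean_connectivity": float(k.mean()),
        })
    table = pd.DataFrame(rows)
    ok = table[table["signed_r2"] >= target_r2]
    if len(ok):
        chosen = int(ok["beta"].iloc[0])
    else:
        chosen = int(table.loc[table["signed_r2"].idxmax(), "beta"])
        warnings.warn(
            f"no candidate beta reached signed R^2 {target_r2}; "
            f"using beta={chosen} (max signed R^2 "
            f"{table['signed_r2'].max():.3f})",
            RuntimeWarning,
            stacklevel=2,
        )
    return SoftThresholdFit(table=table, chosen_beta=chosen, target_r2=target_r2)


def tom_matrix(adj: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Topological overlap: ``(l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)``.

    ``l_ij`` sums shared neighbour weights, ``k_i`` is the connectivity; the
    diagonal is set to 1.
    """
    a = np.asarray(adj, dtype=float).copy()
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / (min_k + 1.0 - a)
    tom[np.isnan(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def cluster_and_cut(
    tom: np.ndarray | pd.DataFrame,
    gene_ids: list[str] | None = None,
    min_size: int = 30,
    cut_height: float | None = None,
) -> ModulePartition:
    """Average-linkage clustering on 1-TOM with a static height cut.

    Merges at height strictly below ``cut_height`` are kept (a merge exactly
    at the cut is split).  When ``cut_height`` is None it defaults to 0.97
    of the maximum merge height, which sits below the band of merges that
    attach unclustered background genes while leaving coherent modules
    intact (a split module is re-united by the eigengene merge stage).
    Clusters smaller than ``min_size`` are assigned the background label;
    retained modules are labelled by decreasing size.
    """
    if isinstance(tom, pd.DataFrame):
        gene_ids = list(tom.index)
        tom = tom.to_numpy()
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(tom.shape[0])]
    diss = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method="average")
    heights = z[:, 2]
    if cut_height is None:
        cut_height = 0.97 * float(heights.max())
    if not (0.0 < cut_height <= 1.0 + 1e-9):
        raise ValueError("cut_height must lie in (0, 1]")
    # strict cut: merges with height == cut_height are not joined
    t = np.nextafter(cut_height, 0.0)
    raw = fcluster(z, t=t, criterion="distance")
    series = pd.Series(raw, index=gene_ids)
    sizes = series.value_counts()
    keep = sizes.index[sizes >= min_size]
    ordered = sizes.loc[keep].sort_values(ascending=False).index
    relabel = {c: f"M{i + 1:02d}" for i, c in enumerate(ordered)}
    module_of_gene = series.map(lambda c: relabel.get(c, BACKGROUND_LABEL))
    module_of_gene.name = "module"
    return ModulePartition(module_of_gene=module_of_gene)


def module_eigengene(
    expr: ExprMatrix | pd.DataFrame, genes: list[str]
) -> tuple[pd.Series, float]:
    """First principal component of a module's standardised expression.

    Returns the unit-norm per-sample eigengene, sign-oriented so that the
    mean gene-eigengene correlation is positive, and the fraction of variance
    explained.
    """
    values = expr.values if isinstance(expr, ExprMatrix) else expr
    if not genes:
        raise ValueError("module is empty")
    sub = values.loc[genes].to_numpy(dtype=float)
    if sub.shape[1] < 2:
        raise ValueError("eigengene needs at least 2 samples")
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mean) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    cors = z @ eig
    if cors.mean() < 0:
        eig = -eig
    eig = eig / np.linalg.norm(eig)
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return pd.Series(eig, index=values.columns, name="eigengene"), var_explained


def _compute_eigengenes(
    expr, partition: ModulePartition
) -> tuple[pd.DataFrame, dict[str, float]]:
    eigs, varexp = {}, {}
    for m in sorted(partition.modules):
        e, v = module_eigengene(expr, partition.genes_in(m))
        eigs[m] = e
        varexp[m] = v
    values = expr.values if isinstance(expr, ExprMatrix) else expr
    frame = pd.DataFrame(eigs, index=values.columns) if eigs else pd.DataFrame()
    return frame, varexp


def merge_modules(
    expr: ExprMatrix | pd.DataFrame,
    partition: ModulePartition,
    merge_threshold: float = 0.15,
) -> ModulePartition:
    """Merge modules whose eigengene dissimilarity (1 - cor) is below threshold.

    Each round merges the single closest qualifying pair (the merged module
    keeps the larger constituent's label), recomputes eigengenes, and repeats
    until no pair qualifies.  The comparison is strict, so a dissimilarity of
    exactly ``merge_threshold`` does not merge.
    """
    module_of_gene = partition.module_of_gene.copy()
    history: list[tuple[str, str]] = []
    while True:
        current = ModulePartition(module_of_gene=module_of_gene,
                                  merge_history=history)
        eigs, varexp = _compute_eigengenes(expr, current)
        mods = list(eigs.columns)
        if len(mods) < 2:
            current.eigengenes, current.variance_explained = eigs, varexp
            return current
        cor = np.corrcoef(eigs.to_numpy().T)
        diss = 1.0 - cor
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if not diss[i, j] < merge_threshold:
            current.eigengenes, current.variance_explained = eigs, varexp
            return current
        a, b = mods[i], mods[j]
        sizes = module_of_gene.value_counts()
        winner, loser = (a, b) if sizes[a] >= sizes[b] else (b, a)
        module_of_gene[module_of_gene == loser] = winner
        history.append((loser, winner))
        logger.info("merged module %s into %s (diss %.3f)", loser, winner,
                    diss[i, j])


def export_edges(
    cor: pd.DataFrame,
    partition: ModulePartition,
    cor_cutoff: float = 0.8,
    beta: int | None = None,
) -> pd.DataFrame:
    """Within-module gene pairs with ``|cor|`` strictly above the cutoff.

    Each undirected pair appears once (gene_a < gene_b); edges are annotated
    with the correlation, the signed adjacency (when beta is given) and the
    module.
    """
    genes = np.asarray(cor.index)
    module = partition.module_of_gene.loc[cor.index].to_numpy()
    c = cor.to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    same = (module[iu] == module[ju]) & (module[iu] != BACKGROUND_LABEL)
    strong = np.abs(c[iu, ju]) > cor_cutoff
    keep = same & strong
    edges = pd.DataFrame({
        "gene_a": genes[iu[keep]],
        "gene_b": genes[ju[keep]],
        "cor": c[iu[keep], ju[keep]],
        "module": module[iu[keep]],
    })
    if beta is not None:
        edges["adj"] = signed_adjacency(edges["cor"].to_numpy(), beta)
        edges = edges[["gene_a", "gene_b", "cor", "adj", "module"]]
    return edges
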