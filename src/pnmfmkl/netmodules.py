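"""Weighted co-expression network, topological overlap and module detection.

The adjacency between genes i and j is ``|PCC(i, j)| ** beta`` with the
soft-threshold power ``beta`` chosen for approximate scale-free topology
(smallest candidate whose log-log connectivity fit reaches the target R^2).
The topological overlap similarity between nodes i != j is

    TOM(i, j) = [sum_{v != i,j} X_iv X_jv + X_ij]
                / [min(sum_{v != i} X_iv, sum_{v != j} X_jv) - X_ij + 1]

(1 on the diagonal), written for Boolean entries but well defined for any
X in [0, 1]; ``dissTOM = 1 - TOM`` feeds average-linkage clustering. Modules
come from cutting the dendrogram at its largest merge heights (everything
above ``cut_height``); branches of at least ``min_module_size`` genes become
modules named by the usual size-ordered color palette, everything else falls
into the grey pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

__all__ = [
    "AdjacencyMatrix",
    "TOMMatrix",
    "GeneModule",
    "ClusterValidityReport",
    "pick_soft_power",
    "adjacency",
    "tom",
    "cut_modules",
    "validity_indices",
    "MODULE_COLORS",
]

logger = logging.getLogger(__name__)

# WGCNA-style size-ordered palette; "grey" is reserved for unassigned genes.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]
UNASSIGNED = "grey"


@dataclass
class AdjacencyMatrix:
    genes: list[str]
    X: np.ndarray
    beta: float
    mode: str = "weighted"  # or "boolean"
    threshold: float | None = None


@dataclass
class TOMMatrix:
    genes: list[str]
    T: np.ndarray

    @property
    def dissT(self) -> np.ndarray:
        return 1.0 - self.T


@dataclass
class GeneModule:
    module_id: str
    genes: list[str]
    mean_pcc: float | None = None


@dataclass
class ClusterValidityReport:
    dunn_index: float
    avg_scaled_connectivity: float
    silhouette_width: float
    avg_cluster_coefficient: float
    avg_max_adjacency_ratio: float
    density: float
    centralization: float
    heterogeneity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Dunn Index": self.dunn_index,
            "Average scaled connectivity": self.avg_scaled_connectivity,
            "Silhouette width": self.silhouette_width,
            "Average cluster coefficient": self.avg_cluster_coefficient,
            "Average maximum adjacency ratio": self.avg_max_adjacency_ratio,
            "Density": self.density,
            "Centralization": self.centralization,
            "Heterogeneity": self.heterogeneity,
        }


def _abs_corr(expr: np.ndarray) -> np.ndarray:
    sd = expr.std(axis=1)
    if (sd == 0).any():
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"constant gene at row {bad}: correlation undefined")
    C = np.corrcoef(expr)
    C = np.clip(np.abs(C), 0.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def scale_free_fit(X: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of the binned connectivity distribution."""
    A = X.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) < 1e-12:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        mean_k = k[sel].mean()
        p_k = sel.sum() / k.size
        if mean_k > 0 and p_k > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(p_k))
    if len(xs) < 3 or np.ptp(xs) < 1e-12:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    if not np.isfinite(r):
        return 0.0
    return float(r * r)


def pick_soft_power(
    expr: np.ndarray,
    powers: list[float] | None = None,
    r2_target: float = 0.8,
) -> tuple[float, dict[float, float]]:
    """Smallest candidate power reaching the scale-free fit target.

    Falls back to the power maximizing R^2 when no candidate reaches it.
    Returns the chosen power and the full power -> R^2 curve.
    """
    if powers is None:
        powers = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
    if len(powers) < 3:
        raise ValueError("need at least 3 candidate powers")
    expr = np.asarray(expr, dtype=float)
    if expr.shape[0] < 10:
        raise ValueError("need at least 10 genes to bin the connectivity distribution")
    C = _abs_corr(expr)
    curve: dict[float, float] = {}
    for b in sorted(powers):
        curve[b] = scale_free_fit(C**b)
    for b in sorted(curve):
        if curve[b] >= r2_target:
            logger.info("soft power %s reaches R^2=%.3f (target %.2f)", b, curve[b], r2_target)
            return b, curve
    best = max(sorted(curve), key=lambda b: curve[b])
    logger.info("no power reaches R^2 target %.2f; using argmax %s (R^2=%.3f)",
                r2_target, best, curve[best])
    return best, curve


def adjacency(
    expr: np.ndarray,
    power: float,
    mode: str = "weighted",
    genes: list[str] | None = None,
    threshold: float = 0.5,
) -> AdjacencyMatrix:
    """Adjacency from absolute Pearson correlation raised to *power*."""
    expr = np.asarray(expr, dtype=float)
    X = _abs_corr(expr) ** power
    if mode == "boolean":
        X = (X >= threshold).astype(float)
        np.fill_diagonal(X, 1.0)
    elif mode != "weighted":
        raise ValueError(f"unknown adjacency mode {mode!r}")
    if genes is None:
        genes = [f"g{i}" for i in range(expr.shape[0])]
    return AdjacencyMatrix(list(genes), X, power, mode, threshold if mode == "boolean" else None)


def tom(adj: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap similarity (diagonal 1, entries in [0, 1])."""
    X = np.asarray(adj.X, dtype=float)
    A = X.copy()
    np.fill_diagonal(A, 0.0)  # self-edges excluded from the neighbor sums
    shared = A @ A  # (i, j): sum over v of X_iv X_jv; v=i, v=j drop out via zero diag
    k = A.sum(axis=1)
    num = shared + A
    den = np.minimum.outer(k, k) - A + 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        T = num / den
    T = np.where(np.isfinite(T), T, 0.0)
    np.fill_diagonal(T, 1.0)
    T = np.clip(0.5 * (T + T.T), 0.0, 1.0)
    return TOMMatrix(list(adj.genes), T)


# ----------------------------------------------------------------------
# dendrogram cut
# ----------------------------------------------------------------------

def cut_modules(
    dissT: np.ndarray,
    genes: list[str] | None = None,
    min_module_size: int = 20,
    cut_height: float = 0.99,
) -> list[GeneModule]:
    """Average-linkage dendrogram cut at the largest merge heights.

    Every merge above ``cut_height`` (on the dissTOM scale, so 0.99 severs
    only near-maximal joins) is cut; the resulting branches of at least
    ``min_module_size`` genes become modules, named by the size-ordered
    color palette, and all remaining genes fall into the grey pool. A
    dendrogram whose root stays below the cut height yields a single module.
    """
    D = np.asarray(dissT, dtype=float)
    n = D.shape[0]
    if genes is None:
        genes = [f"g{i}" for i in range(n)]
    if n < 3:
        raise ValueError("need at least 3 genes to build a dendrogram")
    Z = linkage(squareform(np.clip(0.5 * (D + D.T), 0.0, None), checks=False), method="average")
    labels = fcluster(Z, t=cut_height, criterion="distance")

    accepted: list[list[int]] = []
    unassigned: list[int] = []
    for lab in np.unique(labels):
        members = list(np.flatnonzero(labels == lab))
        if len(members) >= min_module_size:
            accepted.append(members)
        else:
            unassigned.extend(members)

    accepted.sort(key=len, reverse=True)
    modules = [
        GeneModule(MODULE_COLORS[k % len(MODULE_COLORS)], sorted(genes[i] for i in leaves))
        for k, leaves in enumerate(accepted)
    ]
    if unassigned:
        modules.append(GeneModule(UNASSIGNED, sorted(genes[i] for i in unassigned)))
    return modules


def validity_indices(
    adj: AdjacencyMatrix, dissT: np.ndarray, modules: list[GeneModule]
) -> ClusterValidityReport:
    """Standard network-concepts cluster validity indices.

    Dunn = min inter-module dissimilarity / max intra-module diameter;
    silhouette from the dissimilarity matrix; the remaining indices are the
    usual weighted-network concepts (density, centralization, heterogeneity,
    scaled connectivity, clustering coefficient, maximum adjacency ratio).
    """
    X = np.asarray(adj.X, dtype=float)
    D = np.asarray(dissT, dtype=float)
    n = X.shape[0]
    pos = {g: i for i, g in enumerate(adj.genes)}
    real = [m for m in modules if m.module_id != UNASSIGNED]
    if not real:
        raise ValueError("need at least one assigned module")
    idx = [np.asarray([pos[g] for g in m.genes]) for m in real]

    # Dunn index on the dissimilarity
    diameters = []
    for I in idx:
        if I.size < 2:
            logger.warning("module of size 1 skipped in diameter computation")
            continue
        sub = D[np.ix_(I, I)]
        diameters.append(float(sub[~np.eye(I.size, dtype=bool)].max()))
    max_diam = max(diameters) if diameters else float("nan")
    if len(idx) >= 2:
        inter = min(
            float(D[np.ix_(idx[a], idx[b])].min())
            for a in range(len(idx))
            for b in range(a + 1, len(idx))
        )
        dunn = inter / max_diam if max_diam and np.isfinite(max_diam) else float("nan")
    else:
        dunn = float("nan") if not diameters else 0.0

    # silhouette over assigned genes
    if len(idx) >= 2:
        all_idx = np.concatenate(idx)
        labels = np.concatenate([[k] * I.size for k, I in enumerate(idx)])
        sil = float(silhouette_score(D[np.ix_(all_idx, all_idx)], labels, metric="precomputed"))
    else:
        sil = 0.0

    A = X.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    k_max = k.max() if k.max() > 0 else 1.0
    density = float(k.sum() / (n * (n - 1))) if n > 1 else 0.0
    centralization = float(n / (n - 2) * (k_max / (n - 1) - density)) if n > 2 else 0.0
    heterogeneity = float(np.sqrt(np.var(k)) / k.mean()) if k.mean() > 0 else 0.0
    scaled_k = float((k / k_max).mean())
    with np.errstate(invalid="ignore", divide="ignore"):
        tri = np.einsum("ij,jk,ki->i", A, A, A)
        denom = k**2 - (A**2).sum(axis=1)
        cc = np.where(denom > 0, tri / denom, 0.0)
        mar = np.where(k > 0, (A**2).sum(axis=1) / k, 0.0)
    return ClusterValidityReport(
        dunn_index=float(dunn),
        avg_scaled_connectivity=scaled_k,
        silhouette_width=sil,
        avg_cluster_coefficient=float(cc.mean()),
        avg_max_adjacency_ratio=float(mar.mean()),
        density=density,
        centralization=centralization,
        heterogeneity=heterogeneity,
    )
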