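"""Relational block system and penalized non-negative matrix tri-factorization.

A :class:`RelationalSystem` holds heterogeneous object types (genes, samples,
per-layer feature spaces) and the observed inter-type relation matrices
``R[i, j]`` (no within-type blocks). :class:`TriFactorizer` decomposes every
relation as ``R[i, j] ~= G[i] @ S[i, j] @ G[j].T`` with one shared
non-negative factor per object type and one latent relation per type pair,
minimizing

    sum_ij || M_ij * (R_ij - G_i S_ij G_j^T) ||_F^2  +  sum_p tr(G_p^T tau_p G_p)

over ``G_p >= 0`` (``M_ij`` an optional observation mask, ``tau_p`` an
optional symmetric constraint penalty). The solver alternates an exact least
squares update of each ``S_ij`` with hierarchical alternating least squares
(HALS) on each ``G_p``: every column is minimized exactly under the
non-negativity constraint, so each step cannot increase the objective; a
revert-on-increase safeguard additionally guarantees a non-increasing
objective trace for the approximate sub-updates (masked blocks, non-diagonal
penalties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .io import OmicsLayer, SampleAnnotation

__all__ = [
    "RelationalSystem",
    "TriFactorizer",
    "build_relational_system",
    "fit_trifactorization",
    "reconstruct",
]

_EPS = 1e-12


@dataclass
class RelationalSystem:
    """Block matrix of inter-object-type relations.

    Attributes
    ----------
    type_names : list of str
        Ordered object types ``o_1 ... o_p``.
    sizes : dict
        Object count per type.
    relations : dict
        ``(i, j) -> R_ij`` with shape ``(sizes[i], sizes[j])``; absent pairs
        simply carry no block. No ``(i, i)`` entries.
    masks : dict
        Optional boolean observation masks aligned with relations.
    constraints : dict
        Optional symmetric penalty matrix ``tau_p`` per type.
    shifts : dict
        Per-relation additive shift applied to make entries non-negative
        (recorded so the transform is invertible).
    """

    type_names: list[str]
    sizes: dict[str, int]
    relations: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    masks: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    constraints: dict[str, np.ndarray] = field(default_factory=dict)
    shifts: dict[tuple[str, str], float] = field(default_factory=dict)
    index: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (i, j), R in self.relations.items():
            if i == j:
                raise ValueError("within-type relations are not allowed")
            if R.shape != (self.sizes[i], self.sizes[j]):
                raise ValueError(f"relation ({i},{j}) shape {R.shape} inconsistent")
        for p, tau in self.constraints.items():
            if not np.allclose(tau, tau.T, atol=1e-10):
                raise ValueError(f"constraint tau[{p}] must be symmetric")

    def add_relation(
        self,
        i: str,
        j: str,
        R: np.ndarray,
        mask: np.ndarray | None = None,
        shift_nonneg: bool = True,
    ) -> None:
        R = np.asarray(R, dtype=float)
        shift = 0.0
        if shift_nonneg and R.size and np.nanmin(R) < 0:
            shift = -float(np.nanmin(R))
            R = R + shift
        if np.isnan(R).any():
            if mask is None:
                mask = ~np.isnan(R)
            R = np.nan_to_num(R, nan=0.0)
        self.relations[(i, j)] = R
        self.shifts[(i, j)] = shift
        if mask is not None:
            self.masks[(i, j)] = np.asarray(mask, dtype=bool)


def build_relational_system(
    layers: list[OmicsLayer],
    annot: SampleAnnotation,
    collapse_gene_layers: bool = True,
) -> RelationalSystem:
    """Assemble the relational block system from probe-collapsed layers.

    Object types are ``gene``, ``sample`` and one feature space per layer.
    Each layer contributes a (features × samples) data relation plus a binary
    gene-membership relation (gene × features). A layer whose feature ids are
    exactly gene symbols collapses its feature type into the shared gene type
    and contributes a single (gene × sample) block; only one layer can occupy
    that pair, further gene-keyed layers keep their own feature type. Since
    relation entries must be non-negative, each block is shifted by its
    minimum (recorded in ``shifts``); within-block missing values are masked
    out and stored as zeros.
    """
    if not layers:
        raise ValueError("need at least one layer")
    samples = layers[0].sample_ids
    for layer in layers:
        if layer.sample_ids != samples:
            raise ValueError("layers must share an identical ordered sample set")

    genes = sorted({layer.gene_of(f) for layer in layers for f in layer.feature_ids})
    gene_pos = {g: k for k, g in enumerate(genes)}

    sys = RelationalSystem(
        type_names=["gene", "sample"],
        sizes={"gene": len(genes), "sample": len(samples)},
        index={"gene": genes, "sample": list(samples)},
    )
    gene_sample_taken = False
    for layer in layers:
        layer_genes = [layer.gene_of(f) for f in layer.feature_ids]
        is_gene_keyed = layer_genes == layer.feature_ids and set(layer_genes) <= set(genes)
        if collapse_gene_layers and is_gene_keyed and not gene_sample_taken:
            # align rows with the global gene order; genes absent from this
            # layer stay unobserved (masked zeros)
            R = np.zeros((len(genes), len(samples)))
            mask = np.zeros((len(genes), len(samples)), dtype=bool)
            for row, g in enumerate(layer_genes):
                R[gene_pos[g]] = layer.values[row]
                mask[gene_pos[g]] = True
            sys.add_relation("gene", "sample", R, mask=None if mask.all() else mask)
            gene_sample_taken = True
            continue
        ft = f"feat_{layer.layer_name}"
        sys.type_names.append(ft)
        sys.sizes[ft] = layer.n_features
        sys.index[ft] = list(layer.feature_ids)
        member = np.zeros((len(genes), layer.n_features))
        for col, g in enumerate(layer_genes):
            if g in gene_pos:
                member[gene_pos[g], col] = 1.0
        sys.add_relation("gene", ft, member, shift_nonneg=False)
        sys.add_relation(ft, "sample", layer.values)
    if len(sys.type_names) < 2 or not sys.relations:
        raise ValueError("relational system needs at least 2 object types and 1 relation")
    return sys


def _default_ranks(sys: RelationalSystem) -> dict[str, int]:
    return {p: min(int(np.ceil(n / 10)), 50, n) for p, n in sys.sizes.items()}


class TriFactorizer(BaseEstimator):
    """Penalized non-negative tri-factorization of a relational block system.

    Parameters
    ----------
    ranks : dict or None
        Latent rank per object type; default ``min(ceil(n/10), 50)``.
    max_iter : int
        Maximum number of block-coordinate sweeps.
    tol : float
        Relative objective-decrease stopping threshold.
    n_init : int
        Number of seeded restarts; the factorization with the lowest final
        objective is kept (alternating descent is sensitive to its start).
    random_state : int
        Seed for the half-normal factor initialization.

    Attributes
    ----------
    G_ : dict mapping type -> (n_p × r_p) non-negative factor.
    S_ : dict mapping (i, j) -> (r_i × r_j) latent relation.
    objective_trace_ : list of objective values, one per sweep, non-increasing.
    """

    def __init__(
        self,
        ranks: dict[str, int] | None = None,
        max_iter: int = 500,
        tol: float = 1e-6,
        n_init: int = 1,
        random_state: int = 0,
    ):
        self.ranks = ranks
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.random_state = random_state

    # -- objective ---------------------------------------------------------
    def _objective(self, sys: RelationalSystem, G, S) -> float:
        val = 0.0
        for (i, j), R in sys.relations.items():
            E = R - G[i] @ S[(i, j)] @ G[j].T
            if (i, j) in sys.masks:
                E = E * sys.masks[(i, j)]
            val += float((E * E).sum())
        for p, tau in sys.constraints.items():
            val += float(np.trace(G[p].T @ tau @ G[p]))
        return val

    def fit(self, sys: RelationalSystem, y=None) -> "TriFactorizer":
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        ranks = dict(self.ranks) if self.ranks else _default_ranks(sys)
        for p, r in ranks.items():
            if r < 1 or r > sys.sizes[p]:
                raise ValueError(f"rank {r} invalid for type {p!r} of size {sys.sizes[p]}")
        best = None
        for restart in range(max(1, self.n_init)):
            G, S, trace = self._fit_single(sys, ranks, self.random_state + restart)
            if best is None or trace[-1] < best[2][-1]:
                best = (G, S, trace)
        G, S, trace = best
        self.types_ = list(sys.type_names)
        self.ranks_ = ranks
        self.G_ = G
        self.S_ = S
        self.objective_trace_ = trace
        self.system_ = sys
        return self

    def _fit_single(self, sys: RelationalSystem, ranks: dict[str, int], seed: int):
        rng = np.random.default_rng(seed)

        scale = np.mean([np.abs(R).mean() for R in sys.relations.values()]) or 1.0
        G = {
            p: np.abs(rng.standard_normal((sys.sizes[p], ranks[p])))
            * np.sqrt(scale / max(ranks[p], 1))
            for p in sys.type_names
        }
        S = {
            key: np.abs(rng.standard_normal((ranks[key[0]], ranks[key[1]])))
            for key in sys.relations
        }

        trace = [self._objective(sys, G, S)]
        for _ in range(self.max_iter):
            # exact least squares for each S block (given the current G's)
            for (i, j), R in sys.relations.items():
                Gi, Gj = G[i], G[j]
                if (i, j) in sys.masks:
                    S_new = self._masked_s_update(R, sys.masks[(i, j)], Gi, Gj, S[(i, j)])
                else:
                    S_new = np.linalg.pinv(Gi.T @ Gi) @ Gi.T @ R @ Gj @ np.linalg.pinv(Gj.T @ Gj)
                old = S[(i, j)]
                S[(i, j)] = S_new
                if self._objective(sys, G, S) > trace[-1] * (1 + 1e-12) + 1e-15:
                    S[(i, j)] = old  # safeguard: keep the trace monotone

            # multiplicative update for each G_p with pos/neg gradient split
            for p in sys.type_names:
                old = G[p]
                G[p] = self._g_update(sys, G, S, p)
                if self._objective(sys, G, S) > trace[-1] * (1 + 1e-12) + 1e-15:
                    G[p] = old

            obj = self._objective(sys, G, S)
            if obj > trace[-1] * (1 + 1e-9) + 1e-12:
                raise RuntimeError("objective increased: update-rule bug")
            prev = trace[-1]
            trace.append(obj)
            if prev <= 0 or (prev - obj) / prev < self.tol:
                break
        return G, S, trace

    @staticmethod
    def _masked_s_update(R, mask, Gi, Gj, S_old, inner: int = 5):
        """Few gradient steps on S for the masked least-squares subproblem."""
        S = S_old.copy()
        L = (np.linalg.norm(Gi.T @ Gi, 2) * np.linalg.norm(Gj.T @ Gj, 2)) or 1.0
        step = 1.0 / (2.0 * L)
        for _ in range(inner):
            E = (Gi @ S @ Gj.T - R) * mask
            S -= step * 2.0 * (Gi.T @ E @ Gj)
        return S

    @staticmethod
    def _g_update(sys: RelationalSystem, G, S, p):
        """Column-wise non-negative least squares (HALS) update of G_p.

        Every block where G_p appears is brought to the common form
        ``||(A - G_p M) * mask||^2`` (right-hand occurrences transposed);
        each column of G_p is then minimized exactly under non-negativity,
        tracking residuals incrementally. A penalty ``tau_p`` contributes
        its diagonal to the column denominators and its off-diagonal part to
        the gradient (exact for the diagonal / zero penalties used by
        default).
        """
        blocks = []  # (A, M, mask) with A: n_p × n_t, M: r_p × n_t
        for (i, j), R in sys.relations.items():
            mask = sys.masks.get((i, j))
            if i == p:
                blocks.append((R, S[(i, j)] @ G[j].T, mask))
            if j == p:
                blocks.append((R.T, (G[i] @ S[(i, j)]).T, None if mask is None else mask.T))
        if not blocks:
            return G[p]
        Gp = G[p].copy()
        r = Gp.shape[1]
        tau = sys.constraints.get(p)
        tau_diag = np.diag(tau) if tau is not None else None
        tau_off = None
        if tau is not None:
            tau_off = tau - np.diag(np.diag(tau))
            if not np.any(tau_off):
                tau_off = None

        residuals = []
        denoms = []  # per-block per-column denominators (n_p,) or scalar
        for A, M, mask in blocks:
            E = A - Gp @ M
            if mask is not None:
                E = E * mask
                denoms.append(mask @ (M**2).T)  # (n_p, r)
            else:
                denoms.append(np.einsum("kt,kt->k", M, M))  # (r,)
            residuals.append(E)

        for k in range(r):
            num = np.zeros(Gp.shape[0])
            den = np.zeros(Gp.shape[0])
            for (A, M, mask), E, D in zip(blocks, residuals, denoms):
                num += E @ M[k]
                dk = D[:, k] if mask is not None else D[k]
                num += Gp[:, k] * dk
                den += dk
            if tau_diag is not None:
                den = den + tau_diag
            if tau_off is not None:
                num = num - tau_off @ Gp[:, k]
            new = np.where(den > _EPS, np.maximum(num, 0.0) / np.maximum(den, _EPS), Gp[:, k])
            delta = new - Gp[:, k]
            if np.any(delta):
                for (A, M, mask), E in zip(blocks, residuals):
                    upd = np.outer(delta, M[k])
                    if mask is not None:
                        upd = upd * mask
                    E -= upd
                Gp[:, k] = new
        return Gp

    # -- reconstruction ----------------------------------------------------
    def reconstruct(self, i: str, j: str) -> np.ndarray:
        """Approximate relation ``R_hat[i, j] = G[i] @ S[i, j] @ G[j].T``."""
        if (i, j) in self.S_:
            out = self.G_[i] @ self.S_[(i, j)] @ self.G_[j].T
        elif (j, i) in self.S_:
            out = (self.G_[j] @ self.S_[(j, i)] @ self.G_[i].T).T
        else:
            raise KeyError(f"no latent relation between {i!r} and {j!r}")
        if not np.isfinite(out).all():
            raise ValueError("reconstruction contains non-finite entries")
        return out


def fit_trifactorization(
    sys: RelationalSystem,
    ranks: dict[str, int] | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    n_init: int = 1,
) -> TriFactorizer:
    """Functional wrapper over :class:`TriFactorizer`."""
    return TriFactorizer(
        ranks=ranks, max_iter=max_iter, tol=tol, n_init=n_init, random_state=seed
    ).fit(sys)


def reconstruct(fac: TriFactorizer, i: str, j: str) -> np.ndarray:
    """Functional wrapper over :meth:`TriFactorizer.reconstruct`."""
    return fac.reconstruct(i, j)
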