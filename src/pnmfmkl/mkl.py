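"""Hinge-loss soft-margin multiple kernel learning.

Given base kernels ``K_1 ... K_P`` over the same samples with labels
``y in {-1, +1}``, the model learns combination weights ``mu`` (non-negative,
summing to one), a shared SVM dual vector ``alpha`` on the combined kernel
``K_mu = sum_p mu_p K_p``, a target margin ``theta`` and per-kernel slacks
``zeta_p`` minimizing

    -theta + pi * sum_p zeta_p
    s.t.  D_SVM(K_p, alpha) >= theta - zeta_p,   zeta_p >= 0,

where ``D_SVM(K, alpha) = sum_n alpha_n - 1/2 sum_nm alpha_n alpha_m y_n y_m
K(n, m)`` is the SVM dual objective at a fixed dual vector. The trade-off
``pi`` must satisfy ``pi >= 1/P`` for the program to admit a solution.

The solver alternates (a) a single-kernel SVM dual solve on ``K_mu`` (libsvm
through scikit-learn), (b) the closed-form (theta, zeta): with ``k =
ceil(1/pi)``, ``theta`` is the k-th smallest ``D_SVM`` and ``zeta_p =
max(0, theta - D_p)``, and (c) an exponentiated-gradient step on ``mu``
along the per-kernel margin norms ``q_p = alpha^T Y K_p Y alpha`` — the
descent direction of the combined dual value with respect to ``mu`` — which
concentrates weight on kernels that realise a large margin contribution
(equivalently a small ``D_SVM``) and leaves ties at uniform weight. A step
is accepted only if the objective does not increase (backtracking on the
step size), so the recorded objective trace is non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .kernels import KernelSet

__all__ = ["MKLModel", "SoftMarginMKL", "svm_dual_objective", "fit_soft_margin_mkl", "decision_scores"]


class FeasibilityError(ValueError):
    """Raised when constraints make the MKL program unsolvable."""


@dataclass
class MKLModel:
    """Fitted soft-margin MKL solution."""

    alpha: np.ndarray
    y: np.ndarray
    mu: np.ndarray
    theta: float
    zeta: np.ndarray
    hinge: np.ndarray
    d_svm: np.ndarray
    pi: float
    C: float
    b: float
    objective: float
    objective_trace: list[float] = field(default_factory=list)


def svm_dual_objective(
    K: np.ndarray, y: np.ndarray, alpha: np.ndarray, C: float = np.inf
) -> float:
    """SVM dual value ``sum(alpha) - 1/2 alpha^T (yy^T * K) alpha``.

    Requires a feasible ``alpha``: non-negative, below the box constraint,
    and balanced (``sum_n y_n alpha_n = 0`` within 1e-8).
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if (alpha < -1e-12).any():
        raise FeasibilityError("alpha has negative entries")
    if (alpha > C + 1e-8).any():
        raise FeasibilityError(f"alpha exceeds box constraint C={C}")
    bal = float(np.dot(y, alpha))
    if abs(bal) > 1e-8 * max(1.0, float(np.abs(alpha).sum())):
        raise FeasibilityError(f"sum(y * alpha) = {bal:g} != 0")
    ya = alpha * y
    return float(alpha.sum() - 0.5 * ya @ K @ ya)


def _margin_norms(kernels: list[np.ndarray], y: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    ya = alpha * y
    return np.array([float(ya @ K @ ya) for K in kernels])


class SoftMarginMKL(BaseEstimator, ClassifierMixin):
    """Binary classifier over a learned convex combination of base kernels.

    Parameters
    ----------
    pi : float
        Slack trade-off of the hinge-loss objective; must be >= 1/P.
    C : float
        Box constraint of the inner SVM dual.
    max_outer : int
        Maximum alternating iterations.
    eta : float
        Initial exponentiated-gradient step size for the weight update.
    tol : float
        Stop when the objective improves by less than this (relative).

    Attributes
    ----------
    mu_ : per-kernel combination weights (sum to 1).
    alpha_ : dual coefficients on the combined kernel.
    theta_, zeta_, hinge_, d_svm_ : margin, slack and dual quantities at the solution.
    objective_, objective_trace_ : hinge-loss objective value / trace.
    b_ : decision-function intercept (KKT midpoint of free support vectors).
    """

    def __init__(
        self,
        pi: float = 1.0,
        C: float = 1.0,
        max_outer: int = 50,
        eta: float = 1.0,
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.pi = pi
        self.C = C
        self.max_outer = max_outer
        self.eta = eta
        self.tol = tol
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _solve_svm(self, K_mu: np.ndarray, y: np.ndarray) -> np.ndarray:
        svc = SVC(kernel="precomputed", C=self.C, tol=1e-8)
        svc.fit(K_mu, y)
        alpha = np.zeros(y.shape[0])
        alpha[svc.support_] = np.abs(svc.dual_coef_[0])
        # libsvm leaves a tiny balance residual; project it out inside the box
        resid = float(np.dot(y, alpha))
        free = (alpha > 1e-9) & (alpha < self.C - 1e-9)
        if abs(resid) > 0 and free.any():
            adj = resid * y / free.sum()
            alpha[free] -= adj[free]
            alpha = np.clip(alpha, 0.0, self.C)
        return alpha

    def _theta_zeta(self, d: np.ndarray) -> tuple[float, np.ndarray]:
        k = int(np.ceil(1.0 / self.pi))
        theta = float(np.sort(d)[min(k, d.size) - 1])
        zeta = np.maximum(0.0, theta - d)
        return theta, zeta

    def _objective_for(self, kernels, y, mu) -> tuple[float, np.ndarray, np.ndarray]:
        K_mu = sum(m * K for m, K in zip(mu, kernels))
        alpha = self._solve_svm(K_mu, y)
        d = np.array([svm_dual_objective(K, y, alpha, C=self.C) for K in kernels])
        theta, zeta = self._theta_zeta(d)
        return -theta + self.pi * float(zeta.sum()), alpha, d

    def fit(self, kernels: "KernelSet | list[np.ndarray]", y: np.ndarray | None = None):
        if isinstance(kernels, KernelSet):
            mats = [np.asarray(K, float) for K in kernels.kernels]
            if y is None:
                y = kernels.y
        else:
            mats = [np.asarray(K, float) for K in kernels]
        if y is None:
            raise ValueError("labels are required")
        y = np.asarray(y, dtype=float)
        uniq = set(np.unique(y))
        if not uniq <= {-1.0, 1.0} or len(uniq) != 2:
            raise ValueError("labels must be binary in {-1, +1}")
        P = len(mats)
        if self.pi < 1.0 / P - 1e-12:
            raise FeasibilityError(f"pi={self.pi} < 1/P={1.0 / P}: no solution")
        for K in mats:
            w = np.linalg.eigvalsh(0.5 * (K + K.T))
            if w[0] < -1e-8 * max(1.0, abs(w[-1])):
                raise ValueError("base kernel is not positive semidefinite")

        mu = np.full(P, 1.0 / P)
        obj, alpha, d = self._objective_for(mats, y, mu)
        trace = [obj]
        eta = self.eta
        for _ in range(self.max_outer):
            q = _margin_norms(mats, y, alpha)
            if np.ptp(q) < 1e-12:  # all kernels equivalent at this alpha
                break
            step_ok = False
            for _bt in range(12):
                scale = q / max(q.max(), 1e-300)
                mu_new = mu * np.exp(eta * scale)
                mu_new /= mu_new.sum()
                obj_new, alpha_new, d_new = self._objective_for(mats, y, mu_new)
                if obj_new <= obj + 1e-12:
                    step_ok = True
                    break
                eta *= 0.5
            if not step_ok:
                break
            improved = obj - obj_new
            mu, obj, alpha, d = mu_new, obj_new, alpha_new, d_new
            trace.append(obj)
            if improved < self.tol * max(1.0, abs(obj)):
                break

        theta, zeta = self._theta_zeta(d)
        self.mu_ = mu
        self.alpha_ = alpha
        self.y_ = y
        self.d_svm_ = d
        self.theta_ = float(np.min(d + zeta))
        self.zeta_ = zeta
        self.hinge_ = np.maximum(0.0, zeta)
        self.objective_ = obj
        self.objective_trace_ = trace
        self.kernels_ = mats
        self.b_ = self._intercept(mats, y, alpha, mu)
        self.classes_ = np.array([-1.0, 1.0])
        return self

    def _intercept(self, mats, y, alpha, mu) -> float:
        K_mu = sum(m * K for m, K in zip(mu, mats))
        f = (alpha * y) @ K_mu
        free = (alpha > 1e-8) & (alpha < self.C - 1e-8)
        sv = free if free.any() else alpha > 1e-8
        if not sv.any():
            raise ValueError("no support vectors")
        return float(np.mean(y[sv] - f[sv]))

    def combined_kernel(self, mats: list[np.ndarray] | None = None) -> np.ndarray:
        mats = self.kernels_ if mats is None else mats
        return sum(m * K for m, K in zip(self.mu_, mats))

    def decision_function(self, K_cross: list[np.ndarray]) -> np.ndarray:
        """Scores for test samples given per-kernel (n_train × n_test) blocks."""
        K_mu = sum(m * K for m, K in zip(self.mu_, K_cross))
        return (self.alpha_ * self.y_) @ K_mu + self.b_

    def predict(self, K_cross: list[np.ndarray]) -> np.ndarray:
        return np.where(self.decision_function(K_cross) >= 0, 1.0, -1.0)


def fit_soft_margin_mkl(
    kernels: KernelSet,
    pi: float = 1.0,
    C: float = 1.0,
    max_outer: int = 50,
    seed: int = 0,
) -> MKLModel:
    """Functional wrapper returning a plain :class:`MKLModel` record."""
    est = SoftMarginMKL(pi=pi, C=C, max_outer=max_outer, random_state=seed).fit(kernels)
    return MKLModel(
        alpha=est.alpha_,
        y=est.y_,
        mu=est.mu_,
        theta=est.theta_,
        zeta=est.zeta_,
        hinge=est.hinge_,
        d_svm=est.d_svm_,
        pi=pi,
        C=C,
        b=est.b_,
        objective=est.objective_,
        objective_trace=est.objective_trace_,
    )


def decision_scores(
    model: MKLModel, kernels: KernelSet, test_columns: np.ndarray
) -> np.ndarray:
    """Decision scores for the given sample columns of a fitted model.

    ``score_s = sum_n alpha_n y_n K_mu(n, s) + b``; assumes the model was fit
    on the full kernel rows (training samples = all rows of the kernels).
    """
    test_columns = np.asarray(test_columns)
    K_mu = sum(m * K[:, test_columns] for m, K in zip(model.mu, kernels.kernels))
    return (model.alpha * model.y) @ K_mu + model.b
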