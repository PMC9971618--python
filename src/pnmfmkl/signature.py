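"""Gene-signature election and PAM (nearest shrunken centroids) evaluation.

The signature is the module with the maximum mean within-module pairwise
Pearson correlation. Its discriminative value is assessed with the PAM
classifier — class centroids soft-thresholded toward the overall centroid —
under repeated stratified 10-fold cross-validation; sensitivity,
specificity, precision and accuracy are pooled per repeat and summarized as
mean ± standard deviation over repeats, with AUC from pooled posterior
scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_X_y, check_array

from .labelsearch import rank_auc
from .netmodules import GeneModule, UNASSIGNED

__all__ = [
    "SignatureReport",
    "NearestShrunkenCentroids",
    "module_mean_pcc",
    "elect_signature",
    "pam_cv_evaluate",
]

logger = logging.getLogger(__name__)


@dataclass
class SignatureReport:
    """Repeated-CV evaluation of the elected signature module."""

    module_id: str
    genes: list[str]
    mean_pcc: float
    per_repeat: list[dict[str, float]]
    summary: dict[str, tuple[float, float]]  # metric -> (mean, std over repeats)
    mean_auc: float


class NearestShrunkenCentroids(BaseEstimator, ClassifierMixin):
    """PAM: nearest-centroid classification with soft-thresholded centroids.

    Per class k and feature j the standardized centroid difference

        d_kj = (mean_kj - mean_j) / (m_k * (s_j + s0)),   m_k = sqrt(1/n_k - 1/n)

    is shrunk by ``delta`` (soft threshold); shrunken class centroids are
    rebuilt from the surviving d'_kj, and samples are assigned by the
    discriminant score

        delta_k(x) = sum_j (x_j - centroid_kj)^2 / (s_j + s0)^2 - 2 log prior_k.

    ``delta="cv"`` picks the shrinkage on a grid by inner cross-validation.
    At ``delta = 0`` the rule is diagonal-covariance nearest-centroid
    classification.
    """

    def __init__(
        self,
        delta: float | str = 0.0,
        s0: str | float = "median",
        cv_folds: int = 5,
        n_deltas: int = 30,
        random_state: int = 0,
    ):
        self.delta = delta
        self.s0 = s0
        self.cv_folds = cv_folds
        self.n_deltas = n_deltas
        self.random_state = random_state

    # -- core fit at one shrinkage level -------------------------------
    def _fit_once(self, X, y, delta):
        classes = np.unique(y)
        n, p = X.shape
        overall = X.mean(axis=0)
        pooled = np.zeros(p)
        n_k = {}
        means = {}
        for c in classes:
            Xi = X[y == c]
            n_k[c] = Xi.shape[0]
            means[c] = Xi.mean(axis=0)
            pooled += ((Xi - means[c]) ** 2).sum(axis=0)
        dof = max(n - classes.size, 1)
        s = np.sqrt(pooled / dof)
        s0 = float(np.median(s)) if self.s0 == "median" else float(self.s0)
        cent = {}
        d_shr = {}
        for c in classes:
            m_k = np.sqrt(max(1.0 / n_k[c] - 1.0 / n, 1e-12))
            d = (means[c] - overall) / (m_k * (s + s0))
            d2 = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
            d_shr[c] = d2
            cent[c] = overall + m_k * (s + s0) * d2
        return classes, cent, s, s0, {c: n_k[c] / n for c in classes}, d_shr

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        delta = self.delta
        if delta == "cv":
            delta = self._pick_delta(X, y)
        (self.classes_, self.centroids_, self.s_, self.s0_,
         self.priors_, self.d_shrunk_) = self._fit_once(X, y, float(delta))
        self.delta_ = float(delta)
        return self

    def _pick_delta(self, X, y) -> float:
        _, _, s, s0, _, d_raw = self._fit_once(X, y, 0.0)
        d_max = max(float(np.abs(d).max()) for d in d_raw.values())
        grid = np.linspace(0.0, d_max, self.n_deltas)
        n_min = min(np.bincount(np.unique(y, return_inverse=True)[1]))
        folds = max(2, min(self.cv_folds, int(n_min)))
        skf = StratifiedKFold(folds, shuffle=True, random_state=self.random_state)
        acc = np.zeros(grid.size)
        for train, test in skf.split(X, y):
            for gi, dl in enumerate(grid):
                classes, cent, s, s0, priors, _ = self._fit_once(X[train], y[train], dl)
                pred = self._predict_with(X[test], classes, cent, s, s0, priors)
                acc[gi] += float((pred == y[test]).mean())
        # highest accuracy; ties favour stronger shrinkage (simpler model)
        best = np.flatnonzero(acc == acc.max())[-1]
        return float(grid[best])

    @staticmethod
    def _scores_with(X, classes, cent, s, s0, priors):
        sc = np.empty((X.shape[0], classes.size))
        denom = (s + s0) ** 2
        for k, c in enumerate(classes):
            sc[:, k] = ((X - cent[c]) ** 2 / denom).sum(axis=1) - 2.0 * np.log(priors[c])
        return sc

    def _predict_with(self, X, classes, cent, s, s0, priors):
        sc = self._scores_with(X, classes, cent, s, s0, priors)
        return classes[np.argmin(sc, axis=1)]

    def predict(self, X):
        X = check_array(X)
        return self._predict_with(X, self.classes_, self.centroids_, self.s_, self.s0_, self.priors_)

    def predict_proba(self, X):
        X = check_array(X)
        sc = self._scores_with(X, self.classes_, self.centroids_, self.s_, self.s0_, self.priors_)
        logp = -0.5 * sc
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def decision_function(self, X):
        """Binary only: score for the second (larger) class."""
        if self.classes_.size != 2:
            raise ValueError("decision_function is defined for binary problems")
        sc = self._scores_with(check_array(X), self.classes_, self.centroids_, self.s_, self.s0_, self.priors_)
        return 0.5 * (sc[:, 0] - sc[:, 1])

    @property
    def n_active_genes_(self) -> int:
        """Number of features with a nonzero shrunken centroid difference."""
        active = np.zeros_like(self.s_, dtype=bool)
        for d in self.d_shrunk_.values():
            active |= d != 0
        return int(active.sum())


def module_mean_pcc(expr: np.ndarray, module: GeneModule, genes: list[str]) -> float:
    """Mean Pearson correlation over all unordered within-module gene pairs."""
    if len(module.genes) < 2:
        raise ValueError(f"module {module.module_id!r} has fewer than 2 genes")
    pos = {g: i for i, g in enumerate(genes)}
    idx = [pos[g] for g in module.genes]
    C = np.corrcoef(np.asarray(expr, dtype=float)[idx])
    iu = np.triu_indices(len(idx), k=1)
    return float(C[iu].mean())


def elect_signature(
    expr: np.ndarray, modules: list[GeneModule], genes: list[str]
) -> GeneModule:
    """Module with maximal mean within-module PCC (grey pool excluded).

    Ties break toward the larger module, then the lexicographically smaller id.
    """
    eligible = [m for m in modules if m.module_id != UNASSIGNED and len(m.genes) >= 2]
    if not eligible:
        raise ValueError("no eligible module to elect a signature from")
    for m in eligible:
        m.mean_pcc = module_mean_pcc(expr, m, genes)
    return min(eligible, key=lambda m: (-m.mean_pcc, -len(m.genes), m.module_id))


def pam_cv_evaluate(
    expr: np.ndarray,
    genes: list[str],
    signature: GeneModule,
    labels: np.ndarray,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    delta: float | str = "cv",
) -> SignatureReport:
    """Repeated stratified k-fold PAM evaluation of the signature genes.

    Samples are rows after transposition of the (gene × sample) *expr*
    restricted to the signature genes. Per repeat, out-of-fold class
    predictions are pooled into one confusion matrix and out-of-fold
    posterior scores into one AUC; the report carries mean ± std over
    repeats.
    """
    pos = {g: i for i, g in enumerate(genes)}
    idx = [pos[g] for g in signature.genes]
    X = np.asarray(expr, dtype=float)[idx].T  # samples × signature genes
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("PAM evaluation expects binary labels (best combination)")
    pos_class = classes[1]
    n_min = int(min((y == c).sum() for c in classes))
    use_folds = folds if n_min >= folds else max(2, n_min)
    if use_folds != folds:
        logger.warning("reducing folds %d -> %d (smallest class has %d samples)", folds, use_folds, n_min)

    per_repeat: list[dict[str, float]] = []
    for r in range(repeats):
        skf = StratifiedKFold(use_folds, shuffle=True, random_state=seed + r)
        pred = np.empty(y.size, dtype=object)
        score = np.empty(y.size)
        for train, test in skf.split(X, y):
            est = NearestShrunkenCentroids(delta=delta, random_state=seed + r).fit(X[train], y[train])
            pred[test] = est.predict(X[test])
            score[test] = est.predict_proba(X[test])[:, 1]
        is_pos = y == pos_class
        tp = int(((pred == pos_class) & is_pos).sum())
        tn = int(((pred != pos_class) & ~is_pos).sum())
        fp = int(((pred == pos_class) & ~is_pos).sum())
        fn = int(((pred != pos_class) & is_pos).sum())
        per_repeat.append({
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "accuracy": (tp + tn) / y.size,
            "auc": rank_auc(score, is_pos),
        })

    summary = {}
    for key in ("sensitivity", "specificity", "precision", "accuracy", "auc"):
        vals = np.array([m[key] for m in per_repeat], dtype=float)
        summary[key] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
    mean_pcc = signature.mean_pcc
    if mean_pcc is None:
        mean_pcc = module_mean_pcc(expr, signature, genes)
    return SignatureReport(
        module_id=signature.module_id,
        genes=list(signature.genes),
        mean_pcc=float(mean_pcc),
        per_repeat=per_repeat,
        summary=summary,
        mean_auc=summary["auc"][0],
    )
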