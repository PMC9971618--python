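"""Binary class-label combination search scored by cross-validated AUC.

With m classes the candidate binary tasks are every one-vs-one pair plus
every one-vs-rest split (deduplicated under side swap; m = 3 gives the six
classic combinations). Each combination is scored by stratified k-fold
cross-validation of the pipeline's kernel classifier (or PAM on a feature
matrix), pooling out-of-fold decision scores into a Mann-Whitney AUC and
threshold-0 confusion metrics. The combination with the highest AUC wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .io import SampleAnnotation
from .kernels import KernelSet
from .mkl import SoftMarginMKL

__all__ = [
    "LabelCombination",
    "enumerate_combinations",
    "rank_auc",
    "confusion_metrics",
    "score_combination",
    "best_combination",
]

logger = logging.getLogger(__name__)


@dataclass
class LabelCombination:
    """One binary split of the class labels with its CV metrics."""

    left: tuple[str, ...]   # positive side
    right: tuple[str, ...]  # negative side
    metrics: dict[str, float] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"{'+'.join(self.left)} vs {'+'.join(self.right)}"

    @property
    def auc(self) -> float:
        return self.metrics.get("auc", float("nan"))


def enumerate_combinations(classes: list[str]) -> list[LabelCombination]:
    """All one-vs-one and one-vs-rest splits, deduplicated under side swap."""
    classes = sorted(classes)
    m = len(classes)
    if m < 2:
        raise ValueError("need at least 2 classes")
    seen: set[frozenset] = set()
    out: list[LabelCombination] = []
    for a, b in combinations(classes, 2):
        key = frozenset([(a,), (b,)])
        if key not in seen:
            seen.add(key)
            out.append(LabelCombination((a,), (b,)))
    for c in classes:
        rest = tuple(x for x in classes if x != c)
        key = frozenset([(c,), rest])
        if key not in seen:
            seen.add(key)
            out.append(LabelCombination((c,), rest))
    return out


def rank_auc(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """Mann-Whitney AUC from pooled scores (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(is_positive, dtype=bool)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need scores from both classes")
    r = rankdata(scores)
    u = float(r[pos].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def confusion_metrics(scores: np.ndarray, is_positive: np.ndarray, threshold: float = 0.0) -> dict[str, float]:
    """Sensitivity/specificity/PPV/NPV/accuracy at a score threshold, plus AUC."""
    pos = np.asarray(is_positive, dtype=bool)
    pred = np.asarray(scores) >= threshold
    tp = int((pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())

    def _safe(num, den):
        return num / den if den else float("nan")

    return {
        "sensitivity": _safe(tp, tp + fn),
        "specificity": _safe(tn, tn + fp),
        "precision": _safe(tp, tp + fp),
        "npv": _safe(tn, tn + fn),
        "accuracy": (tp + tn) / pos.size,
        "auc": rank_auc(scores, pos),
    }


def _binary_labels(combo: LabelCombination, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample mask for the combination and ±1 labels (left = +1)."""
    left = np.isin(y, combo.left)
    right = np.isin(y, combo.right)
    keep = left | right
    if not left.any() or not right.any():
        raise ValueError(f"combination {combo.name}: one side has no samples")
    return keep, np.where(left[keep], 1.0, -1.0)


def score_combination(
    combo: LabelCombination,
    kernels: KernelSet,
    annot: SampleAnnotation,
    folds: int = 10,
    seed: int = 0,
    pi: float = 1.0,
    C: float = 1.0,
) -> LabelCombination:
    """Fill a combination's metrics by stratified CV of the MKL classifier."""
    y_all = annot.vector(kernels.sample_ids)
    keep, y = _binary_labels(combo, y_all)
    sub = kernels.subset(np.flatnonzero(keep))
    n_min = min(int((y > 0).sum()), int((y < 0).sum()))
    use_folds = folds
    if n_min < folds:
        use_folds = max(2, n_min)
        logger.warning("combination %s: reducing folds %d -> %d", combo.name, folds, use_folds)

    scores = np.empty(y.size)
    skf = StratifiedKFold(n_splits=use_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(np.zeros(y.size), y):
        train_k = [K[np.ix_(train, train)] for K in sub.kernels]
        est = SoftMarginMKL(pi=pi, C=C, random_state=seed).fit(train_k, y[train])
        cross = [K[np.ix_(train, test)] for K in sub.kernels]
        scores[test] = est.decision_function(cross)
    metrics = confusion_metrics(scores, y > 0)
    return LabelCombination(combo.left, combo.right, metrics)


def best_combination(scored: list[LabelCombination]) -> LabelCombination:
    """Max-AUC combination; ties break on accuracy, then lexicographic name."""
    if not scored:
        raise ValueError("no scored combinations")
    return min(
        scored,
        key=lambda c: (-c.auc, -c.metrics.get("accuracy", float("-inf")), c.name),
    )
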