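"""Per-layer empirical-Bayes moderated testing and cross-layer feature union.

The moderated t replaces each feature's sample variance ``s2`` by a posterior
blend with a prior variance ``s0_sq`` pooled across the layer,

    s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    t_mod   = beta_hat / sqrt(s2_post * (1/m1 + 1/m2))

which stabilises variance estimates at small sample sizes. The prior
hyperparameters ``(d0, s0_sq)`` are estimated by moment matching on
``log s2`` against a scaled-F sampling model (the classical empirical-Bayes
estimator for gene-wise variances). With more than two classes the per-group
means feed a moderated one-way F statistic,

    F_mod = [sum_g n_g (mean_g - grand_mean)^2 / (m - 1)] / s2_post

with p-values from the F distribution on (m - 1, d0 + d) degrees of freedom;
for two classes F_mod = t_mod**2 and the two routes agree exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import special, stats

from .io import OmicsLayer, SampleAnnotation

__all__ = [
    "ModeratedStats",
    "SignificantFeatureSet",
    "zero_mean_normalize",
    "drop_missing_features",
    "fit_ebayes",
    "select_significant",
    "union_features",
]

logger = logging.getLogger(__name__)

_D0_CAP = 1e6


@dataclass
class ModeratedStats:
    """Moderated test statistics for every feature of one layer."""

    layer_name: str
    feature_ids: list[str]
    beta_hat: np.ndarray
    s2: np.ndarray
    d: float
    d0: float
    s0_sq: float
    s2_post: np.ndarray
    t_mod: np.ndarray | None
    F_mod: np.ndarray
    p_value: np.ndarray
    group_sizes: dict[str, int]
    contrasts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


@dataclass
class SignificantFeatureSet:
    """Per-gene best significant feature of one layer (p < alpha)."""

    layer_name: str
    genes: dict[str, tuple[str, float]]  # gene -> (feature_id, p_value)
    alpha: float

    @property
    def gene_list(self) -> list[str]:
        """Genes sorted ascending by p-value (ties by gene symbol)."""
        return sorted(self.genes, key=lambda g: (self.genes[g][1], g))


def zero_mean_normalize(layer: OmicsLayer, ddof: int = 0) -> OmicsLayer:
    """Standardize each feature row to mean 0, sd 1 (population sd by default).

    Constant rows have no scale and are dropped with a logged warning.
    """
    if np.isnan(layer.values).any():
        raise ValueError(f"layer {layer.layer_name!r} has missing values; filter first")
    mu = layer.values.mean(axis=1, keepdims=True)
    sd = layer.values.std(axis=1, ddof=ddof, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        dropped = [f for f, k in zip(layer.feature_ids, keep) if not k]
        logger.warning(
            "layer %r: dropping %d constant feature(s): %s",
            layer.layer_name, len(dropped), dropped[:5],
        )
    values = (layer.values[keep] - mu[keep]) / sd[keep]
    return OmicsLayer(
        layer.layer_name,
        values,
        [f for f, k in zip(layer.feature_ids, keep) if k],
        layer.sample_ids,
        layer.feature_to_gene,
    )


def drop_missing_features(layer: OmicsLayer) -> OmicsLayer:
    """Discard every feature containing at least one missing value."""
    keep = ~np.isnan(layer.values).any(axis=1)
    if not keep.any():
        raise ValueError(f"layer {layer.layer_name!r}: all features contain missing values")
    if keep.all():
        return layer
    return OmicsLayer(
        layer.layer_name,
        layer.values[keep],
        [f for f, k in zip(layer.feature_ids, keep) if k],
        layer.sample_ids,
        layer.feature_to_gene,
    )


def _estimate_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0_sq) on log s2.

    Under the scaled-F model, e = log s2 - digamma(d/2) + log(d/2) has
    mean log s0_sq + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2) beyond the sampling term trigamma(d/2); inverting the
    trigamma gives d0.
    """
    pos = s2 > 0
    if not pos.any():
        raise ValueError("all features constant: cannot estimate variance prior")
    z = np.log(s2[pos])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0)) if e.size > 1 else 0.0
    if evar <= 1e-12:
        d0 = _D0_CAP
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        d0 = min(d0, _D0_CAP)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def fit_ebayes(
    layer: OmicsLayer,
    annot: SampleAnnotation,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> ModeratedStats:
    """Fit moderated group-difference statistics for every feature.

    Parameters
    ----------
    layer : OmicsLayer
        Features × samples matrix without missing values.
    annot : SampleAnnotation
        Class label for every sample of the layer.
    d0, s0_sq : float, optional
        Override the estimated prior degrees of freedom / prior variance
        (``d0=0`` recovers the classical unmoderated statistics).
    """
    y = annot.vector(layer.sample_ids)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    groups = {c: np.flatnonzero(y == c) for c in classes}
    for c, idx in groups.items():
        if idx.size < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    X = layer.values
    n = X.shape[1]
    m = len(classes)
    d = float(n - m)

    means = {c: X[:, idx].mean(axis=1) for c, idx in groups.items()}
    rss = np.zeros(X.shape[0])
    for c, idx in groups.items():
        rss += ((X[:, idx] - means[c][:, None]) ** 2).sum(axis=1)
    s2 = rss / d

    if d0 is None:
        d0_hat, s0_hat = _estimate_prior(s2, d)
    else:
        d0_hat = float(d0)
        s0_hat = float(s0_sq) if s0_sq is not None else (
            _estimate_prior(s2, d)[1] if d0_hat > 0 else 0.0
        )
    if d0_hat > 0 and s0_hat <= 0:
        raise ValueError("prior variance must be positive when d0 > 0")
    s2_post = (d0_hat * s0_hat + d * s2) / (d0_hat + d)

    df_total = d0_hat + d
    contrasts: dict[tuple[str, str], np.ndarray] = {}
    t_pairs: dict[tuple[str, str], np.ndarray] = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for a, b in combinations(classes, 2):
            beta = means[a] - means[b]
            scale = np.sqrt(s2_post * (1.0 / groups[a].size + 1.0 / groups[b].size))
            contrasts[(a, b)] = beta
            t_pairs[(a, b)] = beta / scale

        # One-way moderated F: between-group mean square over posterior variance.
        grand = X.mean(axis=1)
        ss_between = np.zeros(X.shape[0])
        for c, idx in groups.items():
            ss_between += idx.size * (means[c] - grand) ** 2
        F = (ss_between / (m - 1)) / s2_post
    F = np.where(np.isfinite(F), F, 0.0)
    p = stats.f.sf(F, m - 1, df_total)

    if m == 2:
        a, b = classes
        beta_hat = contrasts[(a, b)]
        t_mod = t_pairs[(a, b)]
        t_mod = np.where(np.isfinite(t_mod), t_mod, 0.0)
    else:
        # report the largest-|t| pairwise contrast per feature
        t_stack = np.stack([t_pairs[k] for k in sorted(t_pairs)])
        b_stack = np.stack([contrasts[k] for k in sorted(contrasts)])
        pick = np.nanargmax(np.abs(t_stack), axis=0)
        beta_hat = b_stack[pick, np.arange(X.shape[0])]
        t_mod = None

    sizes = {c: int(groups[c].size) for c in classes}
    return ModeratedStats(
        layer_name=layer.layer_name,
        feature_ids=list(layer.feature_ids),
        beta_hat=beta_hat,
        s2=s2,
        d=d,
        d0=d0_hat,
        s0_sq=s0_hat,
        s2_post=s2_post,
        t_mod=t_mod,
        F_mod=F,
        p_value=p,
        group_sizes=sizes,
        contrasts=contrasts,
    )


def select_significant(
    stats_: ModeratedStats,
    mapping: dict[str, str] | None = None,
    alpha: float = 0.05,
    adjust: str = "none",
) -> SignificantFeatureSet:
    """Keep features with p < alpha and collapse to one best feature per gene.

    Per gene the minimum-p feature represents it; exact p ties break on the
    lexicographically smallest feature id. ``adjust="bh"`` applies
    Benjamini-Hochberg before thresholding (off by default).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(stats_.p_value, dtype=float)
    if adjust == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * p.size / (np.arange(p.size) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        p_use = np.empty_like(p)
        p_use[order] = np.minimum(adj, 1.0)
    elif adjust == "none":
        p_use = p
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    best: dict[str, tuple[str, float]] = {}
    for fid, pv in zip(stats_.feature_ids, p_use):
        if not pv < alpha:
            continue
        gene = mapping.get(fid, fid) if mapping else fid
        if gene not in best or (pv, fid) < (best[gene][1], best[gene][0]):
            best[gene] = (fid, float(pv))
    if not best:
        logger.info("layer %r: no significant features at alpha=%g", stats_.layer_name, alpha)
    return SignificantFeatureSet(stats_.layer_name, best, alpha)


def union_features(sets: list[SignificantFeatureSet]) -> list[str]:
    """Sorted union of gene symbols across the per-layer significant sets."""
    if not sets:
        raise ValueError("need at least one significant set")
    genes: set[str] = set()
    for s in sets:
        genes |= set(s.genes)
    return sorted(genes)
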