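import numpy as np
import pytest

from pnmfmkl.netmodules import GeneModule
from pnmfmkl.signature import (
    NearestShrunkenCentroids,
    elect_signature,
    module_mean_pcc,
    pam_cv_evaluate,
)


def nearest_centroid_oracle(X_train, y_train, X_test, s0):
    """Longhand diagonal-covariance nearest-centroid rule (equal priors)."""
    classes = sorted(set(y_train))
    n, p = X_train.shape
    cents = {c: X_train[np.array(y_train) == c].mean(axis=0) for c in classes}
    pooled = np.zeros(p)
    for c in classes:
        Xi = X_train[np.array(y_train) == c]
        pooled += ((Xi - cents[c]) ** 2).sum(axis=0)
    s = np.sqrt(pooled / (n - len(classes)))
    preds = []
    for x in X_test:
        dists = [sum((x[j] - cents[c][j]) ** 2 / (s[j] + s0) ** 2 for j in range(p)) for c in classes]
        preds.append(classes[int(np.argmin(dists))])
    return np.array(preds)


# ------------------------------------------------------------ mean PCC

def test_mean_pcc_perfectly_correlated_pair():
    t = np.arange(10.0)
    expr = np.vstack([t, 3 * t + 2])
    mod = GeneModule("m", ["g0", "g1"])
    assert module_mean_pcc(expr, mod, ["g0", "g1"]) == pytest.approx(1.0)


def test_mean_pcc_prescribed_correlations():
    # exact target correlations via whitening + Cholesky
    C = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]])
    rng = np.random.default_rng(0)
    Z = rng.standard_normal((3, 500))
    Z -= Z.mean(axis=1, keepdims=True)
    cov = Z @ Z.T / Z.shape[1]
    Zw = np.linalg.solve(np.linalg.cholesky(cov), Z)  # empirical covariance = I
    white = np.linalg.cholesky(C) @ Zw                # empirical correlation = C
    genes = ["a", "b", "c"]
    got = module_mean_pcc(white, GeneModule("m", genes), genes)
    # pair-loop oracle on the constructed data
    ref = np.mean([np.corrcoef(white[i], white[j])[0, 1] for i, j in [(0, 1), (0, 2), (1, 2)]])
    assert got == pytest.approx(ref, abs=1e-12)
    assert got == pytest.approx(0.4, abs=1e-9)


def test_mean_pcc_independent_genes_near_zero():
    rng = np.random.default_rng(1)
    expr = rng.standard_normal((10, 2000))
    genes = [f"g{i}" for i in range(10)]
    val = module_mean_pcc(expr, GeneModule("m", genes), genes)
    assert abs(val) < 0.05


def test_mean_pcc_requires_two_genes():
    with pytest.raises(ValueError):
        module_mean_pcc(np.zeros((2, 5)), GeneModule("m", ["g0"]), ["g0", "g1"])


# ------------------------------------------------------------ election

def test_elect_signature_prefers_tight_block():
    rng = np.random.default_rng(2)
    n = 200
    f = rng.standard_normal(n)
    tight = [np.sqrt(0.9) * f + np.sqrt(0.1) * rng.standard_normal(n) for _ in range(10)]
    g = rng.standard_normal(n)
    loose = [np.sqrt(0.2) * g + np.sqrt(0.8) * rng.standard_normal(n) for _ in range(10)]
    expr = np.vstack(tight + loose)
    genes = [f"g{i}" for i in range(20)]
    mods = [GeneModule("blue", genes[10:]), GeneModule("turquoise", genes[:10]),
            GeneModule("grey", [])]
    best = elect_signature(expr, mods, genes)
    assert best.module_id == "turquoise"
    assert best.mean_pcc > 0.7


def test_elect_signature_single_and_tie():
    t = np.arange(12.0)
    rng = np.random.default_rng(0)
    expr = np.vstack([t + 0.01 * rng.standard_normal(12) for _ in range(6)])
    genes = [f"g{i}" for i in range(6)]
    only = [GeneModule("m", genes)]
    assert elect_signature(expr, only, genes).module_id == "m"
    # identical correlation structure, different sizes -> larger wins
    dup = np.vstack([t, 2 * t, 3 * t, 4 * t, 5 * t])
    dgenes = [f"h{i}" for i in range(5)]
    mods = [GeneModule("small", dgenes[:2]), GeneModule("large", dgenes[2:])]
    assert elect_signature(dup, mods, dgenes).module_id == "large"


# ------------------------------------------------------------------- PAM

def test_pam_delta_zero_equals_nearest_centroid_oracle():
    X = np.array([[0.0, 0.1], [0.2, -0.1], [0.1, 0.0],
                  [2.0, 1.9], [2.1, 2.2], [1.9, 2.0]])
    y = np.array(["a", "a", "a", "b", "b", "b"])
    est = NearestShrunkenCentroids(delta=0.0).fit(X, y)
    grid = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [0.5, 1.5], [-1.0, 3.0]])
    ref = nearest_centroid_oracle(X, y, grid, est.s0_)
    np.testing.assert_array_equal(est.predict(grid), ref)


def test_pam_shrinkage_monotone_gene_elimination():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((40, 25))
    y = np.array(["a"] * 20 + ["b"] * 20)
    X[y == "b", :5] += 1.0
    counts = []
    for delta in np.linspace(0, 4, 9):
        est = NearestShrunkenCentroids(delta=float(delta)).fit(X, y)
        counts.append(est.n_active_genes_)
    assert all(b <= a for a, b in zip(counts, counts[1:]))


def test_pam_cv_separable_signature():
    rng = np.random.default_rng(4)
    n = 60
    expr = rng.standard_normal((30, n))
    labels = np.array(["neg"] * (n // 2) + ["pos"] * (n // 2))
    sig_genes = [f"g{i}" for i in range(10)]
    genes = sig_genes + [f"g{i}" for i in range(10, 30)]
    expr[:10, labels == "pos"] += 3.0  # strong planted shift on the signature
    mod = GeneModule("turquoise", sig_genes, mean_pcc=0.9)
    rep = pam_cv_evaluate(expr, genes, mod, labels, folds=5, repeats=3, seed=0)
    assert rep.summary["accuracy"][0] >= 0.95
    assert rep.summary["auc"][0] >= 0.98
    for key, (mean, std) in rep.summary.items():
        assert 0.0 <= mean <= 1.0 and std >= 0.0


def test_pam_cv_null_labels_near_chance():
    rng = np.random.default_rng(5)
    n = 80
    expr = rng.standard_normal((20, n))
    labels = np.array(["neg", "pos"] * (n // 2))[rng.permutation(n)]
    genes = [f"g{i}" for i in range(20)]
    mod = GeneModule("m", genes[:8], mean_pcc=0.1)
    rep = pam_cv_evaluate(expr, genes, mod, labels, folds=5, repeats=3, seed=1)
    assert 0.4 <= rep.summary["auc"][0] <= 0.6


def test_pam_report_metrics_match_pooled_confusion():
    # recomputing the metrics from the per-repeat confusion identities
    rng = np.random.default_rng(6)
    n = 40
    expr = rng.standard_normal((10, n))
    labels = np.array(["neg"] * 20 + ["pos"] * 20)
    expr[:4, labels == "pos"] += 1.5
    genes = [f"g{i}" for i in range(10)]
    mod = GeneModule("m", genes[:4], mean_pcc=0.5)
    rep = pam_cv_evaluate(expr, genes, mod, labels, folds=4, repeats=2, seed=2)
    for m in rep.per_repeat:
        # sensitivity, specificity and accuracy are consistent with each other
        acc = (m["sensitivity"] * 20 + m["specificity"] * 20) / 40
        assert m["accuracy"] == pytest.approx(acc, abs=1e-12)
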