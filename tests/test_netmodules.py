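import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from pnmfmkl.netmodules import (
    AdjacencyMatrix,
    adjacency,
    cut_modules,
    pick_soft_power,
    tom,
    validity_indices,
    UNASSIGNED,
)


def tom_oracle(X):
    """Triple-loop evaluation of the topological overlap similarity."""
    n = X.shape[0]
    T = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = sum(X[i, v] * X[j, v] for v in range(n) if v not in (i, j)) + X[i, j]
            ki = sum(X[i, v] for v in range(n) if v != i)
            kj = sum(X[j, v] for v in range(n) if v != j)
            T[i, j] = num / (min(ki, kj) - X[i, j] + 1.0)
    return T


def _adj(X):
    return AdjacencyMatrix([f"g{i}" for i in range(X.shape[0])], X, beta=1.0)


# --------------------------------------------------------------------- tom

def test_tom_complete_boolean_triangle_is_one():
    X = np.ones((3, 3))
    T = tom(_adj(X)).T
    assert np.allclose(T, 1.0)


def test_tom_empty_graph():
    X = np.eye(4)
    T = tom(_adj(X)).T
    np.testing.assert_array_equal(T, np.eye(4))


@pytest.mark.parametrize("boolean", [False, True])
def test_tom_matches_triple_loop_oracle(boolean):
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 16))
        X = rng.random((n, n))
        X = 0.5 * (X + X.T)
        if boolean:
            X = (X > 0.5).astype(float)
        np.fill_diagonal(X, 1.0)
        T = tom(_adj(X)).T
        np.testing.assert_allclose(T, tom_oracle(X), atol=1e-12)
        assert T.min() >= 0.0 and T.max() <= 1.0
        np.testing.assert_allclose(T, T.T, atol=1e-15)
        tm = tom(_adj(X))
        np.testing.assert_allclose(tm.dissT, 1.0 - tm.T, atol=1e-15)


# --------------------------------------------------------------- adjacency

def test_adjacency_power_one_equals_abs_corr_oracle():
    rng = np.random.default_rng(0)
    expr = rng.standard_normal((6, 30))
    X = adjacency(expr, power=1).X
    for i in range(6):
        for j in range(6):
            xi, xj = expr[i], expr[j]
            r = np.sum((xi - xi.mean()) * (xj - xj.mean())) / (
                np.sqrt(np.sum((xi - xi.mean()) ** 2)) * np.sqrt(np.sum((xj - xj.mean()) ** 2))
            )
            assert X[i, j] == pytest.approx(abs(r), abs=1e-12)


def test_adjacency_extreme_correlations():
    t = np.linspace(0, 1, 10)
    expr = np.vstack([t, 2 * t + 1, -3 * t])
    X = adjacency(expr, power=4).X
    assert X[0, 1] == pytest.approx(1.0)
    assert X[0, 2] == pytest.approx(1.0)  # unsigned network


def test_adjacency_constant_gene_errors():
    expr = np.vstack([np.ones(8), np.arange(8.0)])
    with pytest.raises(ValueError):
        adjacency(expr, power=1)


def test_adjacency_boolean_mode():
    rng = np.random.default_rng(1)
    expr = rng.standard_normal((5, 40))
    X = adjacency(expr, power=2, mode="boolean", threshold=0.1).X
    assert set(np.unique(X)) <= {0.0, 1.0}


# -------------------------------------------------------------- soft power

def test_pick_soft_power_scale_free_network():
    # hub-structured data: gene i loads on a shared factor with weight ~ 1/sqrt(rank)
    rng = np.random.default_rng(0)
    n_genes, n_samp = 120, 300
    f = rng.standard_normal(n_samp)
    w = 1.0 / np.sqrt(np.arange(1, n_genes + 1))
    expr = np.outer(w, f) + 0.6 * rng.standard_normal((n_genes, n_samp))
    power, curve = pick_soft_power(expr, powers=list(range(1, 13)), r2_target=0.8)
    assert curve[power] >= 0.8


def test_pick_soft_power_zero_target_returns_smallest():
    rng = np.random.default_rng(1)
    expr = rng.standard_normal((20, 15))
    power, _ = pick_soft_power(expr, powers=[2, 5, 9], r2_target=0.0)
    assert power == 2


def test_pick_soft_power_degenerate_equal_correlations():
    t = np.linspace(0, 1, 12)
    expr = np.vstack([t * (i + 1) + i for i in range(12)])  # all pairwise |r| = 1
    power, curve = pick_soft_power(expr, powers=[1, 2, 3])
    assert power in curve  # fallback branch exercised without error


def test_pick_soft_power_needs_genes():
    with pytest.raises(ValueError):
        pick_soft_power(np.random.default_rng(0).standard_normal((5, 10)))


# ------------------------------------------------------------------- cut

def test_cut_modules_recovers_two_planted_blocks(planted_two_blocks):
    expr, truth = planted_two_blocks
    adj = adjacency(expr, power=6)
    T = tom(adj)
    mods = cut_modules(T.dissT, genes=adj.genes, min_module_size=20)
    real = [m for m in mods if m.module_id != UNASSIGNED]
    assert len(real) == 2
    labels = {}
    for k, m in enumerate(real):
        for g in m.genes:
            labels[g] = k
    pred = [labels.get(g, -1) for g in adj.genes]
    assert adjusted_rand_score(truth, pred) >= 0.9


def test_cut_modules_single_homogeneous_block():
    rng = np.random.default_rng(3)
    f = rng.standard_normal(80)
    expr = np.vstack([np.sqrt(0.9) * f + np.sqrt(0.1) * rng.standard_normal(80) for _ in range(50)])
    adj = adjacency(expr, power=2)
    mods = cut_modules(tom(adj).dissT, genes=adj.genes, min_module_size=10)
    assert len(mods) == 1
    assert len(mods[0].genes) == 50


def test_cut_modules_size_gate(planted_two_blocks):
    expr, _ = planted_two_blocks
    adj = adjacency(expr, power=6)
    mods = cut_modules(tom(adj).dissT, genes=adj.genes, min_module_size=70)
    real = [m for m in mods if m.module_id != UNASSIGNED]
    assert len(real) <= 1


def test_cut_modules_gene_order_invariant(planted_two_blocks):
    expr, _ = planted_two_blocks
    rng = np.random.default_rng(0)
    perm = rng.permutation(expr.shape[0])
    adj1 = adjacency(expr, power=6)
    adj2 = adjacency(expr[perm], power=6,
                     genes=[adj1.genes[i] for i in perm])
    m1 = cut_modules(tom(adj1).dissT, genes=adj1.genes, min_module_size=20)
    m2 = cut_modules(tom(adj2).dissT, genes=adj2.genes, min_module_size=20)
    sets1 = sorted(frozenset(m.genes) for m in m1 if m.module_id != UNASSIGNED)
    sets2 = sorted(frozenset(m.genes) for m in m2 if m.module_id != UNASSIGNED)
    assert sets1 == sets2


def test_cut_modules_too_few_genes():
    with pytest.raises(ValueError):
        cut_modules(np.zeros((2, 2)), min_module_size=1)


# ---------------------------------------------------------------- validity

def test_validity_indices_separated_beats_noisy(planted_two_blocks):
    expr, _ = planted_two_blocks
    adj = adjacency(expr, power=6)
    T = tom(adj)
    mods = cut_modules(T.dissT, genes=adj.genes, min_module_size=20)
    good = validity_indices(adj, T.dissT, mods)

    rng = np.random.default_rng(1)
    noise = rng.standard_normal(expr.shape)
    adj_n = adjacency(noise, power=6, genes=adj.genes)
    T_n = tom(adj_n)
    bad = validity_indices(adj_n, T_n.dissT, mods)  # same partition, noise network
    assert good.dunn_index > bad.dunn_index
    assert good.silhouette_width > bad.silhouette_width
    assert 0.0 <= good.density <= 1.0
    assert -1.0 <= good.silhouette_width <= 1.0


def test_validity_heterogeneity_zero_for_equal_adjacency():
    X = np.full((30, 30), 0.4)
    np.fill_diagonal(X, 1.0)
    adj = AdjacencyMatrix([f"g{i}" for i in range(30)], X, beta=1.0)
    from pnmfmkl.netmodules import GeneModule
    mods = [GeneModule("turquoise", adj.genes[:15]), GeneModule("blue", adj.genes[15:])]
    rep = validity_indices(adj, 1.0 - X, mods)
    assert rep.heterogeneity == pytest.approx(0.0, abs=1e-12)
    assert rep.density == pytest.approx(0.4, abs=1e-12)
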