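import numpy as np
import pytest

from pnmfmkl.diffexp import (
    drop_missing_features,
    fit_ebayes,
    select_significant,
    union_features,
    zero_mean_normalize,
    SignificantFeatureSet,
)
from pnmfmkl.io import SampleAnnotation

from conftest import make_layer


def pooled_t_oracle(x1, x2):
    """Classical two-sample pooled-variance t, computed longhand."""
    m1, m2 = len(x1), len(x2)
    sp2 = (sum((v - np.mean(x1)) ** 2 for v in x1) + sum((v - np.mean(x2)) ** 2 for v in x2)) / (m1 + m2 - 2)
    return (np.mean(x1) - np.mean(x2)) / np.sqrt(sp2 * (1 / m1 + 1 / m2))


# ---------------------------------------------------------------- normalize

def test_zero_mean_normalize_rows_standardized():
    layer = make_layer([[1.0, 2.0, 3.0], [10.0, 0.0, 5.0]])
    out = zero_mean_normalize(layer)
    np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(out.values.std(axis=1), 1.0, atol=1e-12)


def test_zero_mean_normalize_drops_constant_rows():
    layer = make_layer([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
    out = zero_mean_normalize(layer)
    assert out.feature_ids == ["f1"]


def test_zero_mean_normalize_idempotent():
    layer = make_layer(np.random.default_rng(0).standard_normal((4, 9)))
    once = zero_mean_normalize(layer)
    twice = zero_mean_normalize(once)
    np.testing.assert_allclose(twice.values, once.values, atol=1e-12)


def test_drop_missing_features_counts():
    vals = np.random.default_rng(1).standard_normal((10, 4))
    vals[3, 2] = np.nan
    out = drop_missing_features(make_layer(vals))
    assert out.n_features == 9 and "f3" not in out.feature_ids
    # no missing -> identity
    out2 = drop_missing_features(out)
    assert out2.feature_ids == out.feature_ids


def test_drop_missing_all_rows_errors():
    vals = np.full((3, 2), np.nan)
    with pytest.raises(ValueError):
        drop_missing_features(make_layer(vals))


# ---------------------------------------------------------------- ebayes

def test_moderated_t_at_d0_zero_equals_classical_pooled_t(two_group_layer):
    layer, annot = two_group_layer
    stats = fit_ebayes(layer, annot, d0=0.0)
    for i in range(layer.n_features):
        t_ref = pooled_t_oracle(layer.values[i, :6], layer.values[i, 6:])
        assert stats.t_mod[i] == pytest.approx(t_ref, abs=1e-10)
    np.testing.assert_allclose(stats.s2_post, stats.s2, rtol=1e-12)


def test_large_d0_pulls_posterior_variance_to_prior(two_group_layer):
    layer, annot = two_group_layer
    stats = fit_ebayes(layer, annot, d0=1e9, s0_sq=2.5)
    np.testing.assert_allclose(stats.s2_post, 2.5, rtol=1e-6)


def test_posterior_variance_is_convex_combination(two_group_layer):
    layer, annot = two_group_layer
    stats = fit_ebayes(layer, annot)
    lo = np.minimum(stats.s2, stats.s0_sq)
    hi = np.maximum(stats.s2, stats.s0_sq)
    assert np.all(stats.s2_post >= lo - 1e-12) and np.all(stats.s2_post <= hi + 1e-12)


def test_label_swap_flips_t_keeps_F_and_p(two_group_layer):
    layer, annot = two_group_layer
    swapped = SampleAnnotation({s: ("B" if c == "A" else "A") for s, c in annot.labels.items()})
    a = fit_ebayes(layer, annot)
    b = fit_ebayes(layer, swapped)
    np.testing.assert_allclose(a.t_mod, -b.t_mod, atol=1e-12)
    np.testing.assert_allclose(a.F_mod, b.F_mod, atol=1e-12)
    np.testing.assert_allclose(a.p_value, b.p_value, atol=1e-12)


def test_two_class_F_equals_t_squared(two_group_layer):
    layer, annot = two_group_layer
    stats = fit_ebayes(layer, annot)
    np.testing.assert_allclose(stats.F_mod, stats.t_mod**2, rtol=1e-10)


def test_null_pvalues_calibrated():
    rng = np.random.default_rng(123)
    layer = make_layer(rng.standard_normal((1000, 30)))
    annot = SampleAnnotation(
        {s: ("A" if i < 15 else "B") for i, s in enumerate(layer.sample_ids)}
    )
    stats = fit_ebayes(layer, annot)
    frac = float((stats.p_value < 0.05).mean())
    assert 0.03 <= frac <= 0.07


def test_three_class_F_has_uniform_null_p():
    rng = np.random.default_rng(5)
    layer = make_layer(rng.standard_normal((800, 30)))
    annot = SampleAnnotation(
        {s: f"c{i % 3}" for i, s in enumerate(layer.sample_ids)}
    )
    stats = fit_ebayes(layer, annot)
    assert stats.t_mod is None
    frac = float((stats.p_value < 0.05).mean())
    assert 0.02 <= frac <= 0.08


def test_fit_ebayes_requires_two_per_class():
    layer = make_layer(np.random.default_rng(0).standard_normal((5, 4)))
    annot = SampleAnnotation({"s0": "A", "s1": "A", "s2": "A", "s3": "B"})
    with pytest.raises(ValueError):
        fit_ebayes(layer, annot)


# ---------------------------------------------------------------- selection

def _stats_with_p(feature_ids, p):
    from pnmfmkl.diffexp import ModeratedStats

    k = len(feature_ids)
    return ModeratedStats(
        layer_name="L", feature_ids=list(feature_ids),
        beta_hat=np.zeros(k), s2=np.ones(k), d=4.0, d0=0.0, s0_sq=1.0,
        s2_post=np.ones(k), t_mod=np.zeros(k), F_mod=np.zeros(k),
        p_value=np.asarray(p, dtype=float), group_sizes={"A": 3, "B": 3},
    )


def test_select_significant_min_p_per_gene_and_tiebreak():
    stats = _stats_with_p(["p1", "p2", "p3", "p4"], [0.03, 0.01, 0.2, 0.01])
    mapping = {"p1": "G", "p2": "G", "p3": "G", "p4": "H"}
    out = select_significant(stats, mapping, alpha=0.05)
    assert out.genes["G"] == ("p2", 0.01)
    # exact tie -> lexicographically smallest feature id
    stats2 = _stats_with_p(["pb", "pa"], [0.01, 0.01])
    out2 = select_significant(stats2, {"pb": "G", "pa": "G"}, alpha=0.05)
    assert out2.genes["G"][0] == "pa"


def test_select_significant_monotone_in_alpha():
    rng = np.random.default_rng(3)
    p = rng.random(50)
    stats = _stats_with_p([f"f{i}" for i in range(50)], p)
    small = set(select_significant(stats, alpha=0.02).genes)
    large = set(select_significant(stats, alpha=0.2).genes)
    assert small <= large


def test_select_significant_empty_allowed():
    stats = _stats_with_p(["a", "b"], [0.5, 0.9])
    assert select_significant(stats, alpha=0.05).genes == {}


def test_union_features_sorted_dedup():
    s1 = SignificantFeatureSet("l1", {"B": ("f1", 0.01), "A": ("f2", 0.02)}, 0.05)
    s2 = SignificantFeatureSet("l2", {"B": ("g1", 0.03), "C": ("g2", 0.04)}, 0.05)
    assert union_features([s1, s2]) == ["A", "B", "C"]
    assert union_features([s1]) == ["A", "B"]
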