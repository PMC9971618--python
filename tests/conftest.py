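import numpy as np
import pytest

from pnmfmkl.io import OmicsLayer, SampleAnnotation


def make_layer(values, feature_ids=None, sample_ids=None, name="layer", mapping=None):
    values = np.asarray(values, dtype=float)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(values.shape[0])]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(values.shape[1])]
    return OmicsLayer(name, values, feature_ids, sample_ids, mapping)


@pytest.fixture
def two_group_layer():
    """20 features × 12 samples, two classes of 6, seeded Gaussian noise."""
    rng = np.random.default_rng(42)
    values = rng.standard_normal((20, 12))
    layer = make_layer(values, name="expr")
    annot = SampleAnnotation({s: ("A" if i < 6 else "B") for i, s in enumerate(layer.sample_ids)})
    return layer, annot


@pytest.fixture
def planted_two_blocks():
    """Expression with two 60-gene equicorrelated blocks (rho .9 / .8) + labels."""
    rng = np.random.default_rng(7)
    n = 100
    rows = []
    truth = []
    for b, rho in enumerate((0.9, 0.8)):
        f = rng.standard_normal(n)
        for _ in range(60):
            rows.append(np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(n))
            truth.append(b)
    expr = np.asarray(rows)
    return expr, np.asarray(truth)
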