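import numpy as np
import pytest

import promlm as P


@pytest.fixture(scope="session")
def tiny_layer1():
    """Small noise-free two-class dataset with verbatim planted motifs."""
    spec = P.SyntheticSpec(n_pos=30, n_neg=30, per_position_mutation_rate=0.0,
                           strength_mutation_gap=0.0, seed=2)
    layer1, layer2 = P.generate(spec)
    return spec, layer1, layer2


@pytest.fixture(scope="session")
def small_noisy_layer1():
    spec = P.SyntheticSpec(n_pos=60, n_neg=60, seed=9)
    layer1, _ = P.generate(spec)
    return spec, layer1


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_table(rng):
    X = rng.normal(size=(24, 6))
    y = np.array([0, 1] * 12)
    return P.FeatureTable(
        sample_ids=[f"s{i}" for i in range(24)],
        matrix=X,
        feature_names=[f"f{j}" for j in range(6)],
        labels=y,
    )
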