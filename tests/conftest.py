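import numpy as np
import pytest

from metsir.synthetic import GeneratorConfig, make_dataset


@pytest.fixture
def rng():
    """Fresh deterministic generator per test: results do not depend on the
    order in which tests run or on which subset is selected."""
    return np.random.default_rng(20231223)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced two-class dataset for fast integration tests."""
    cfg = GeneratorConfig.strong_signal(effect=6.0, seed=7, n_mets=12,
                                        n_nomets=28)
    return make_dataset(cfg)


@pytest.fixture(scope="session")
def study_dataset():
    """Study-sized dataset: 19 MetS / 86 controls, strong spectral signal."""
    cfg = GeneratorConfig.strong_signal(effect=6.0, seed=1)
    return make_dataset(cfg)


@pytest.fixture
def two_class_matrix(rng):
    """Well-separated isotropic two-class matrix (n=60, p=5)."""
    n1, n2, p = 30, 30, 5
    X = np.vstack([rng.normal(0, 1, (n1, p)), rng.normal(0, 1, (n2, p))])
    X[n1:, 0] += 6.0
    X[n1:, 1] -= 6.0
    y = np.array(["A"] * n1 + ["B"] * n2, dtype=object)
    return X, y
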