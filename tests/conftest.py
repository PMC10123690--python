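import numpy as np
import pytest

from ddtpso.classify import FeatureDataset
from ddtpso.feature_selection import FSConfig
from ddtpso.optimizers import OptimizerConfig
from ddtpso.synthetic import SyntheticSpec, gen_feature_dataset


@pytest.fixture(scope="session")
def standard_dataset():
    """The default synthetic fixture: 200 samples, 5 informative / 3 redundant /
    12 noise features, 2 classes, separation 3, seed 7."""
    dataset, informative = gen_feature_dataset(SyntheticSpec())
    return dataset, informative


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny separable two-class dataset for fast exact checks."""
    rng = np.random.default_rng(0)
    n = 60
    labels = np.array(["a", "b"] * (n // 2))
    x = rng.normal(scale=0.5, size=(n, 4))
    x += 6.0 * (labels == "b")[:, None]
    return FeatureDataset(x, labels)


@pytest.fixture
def fast_fs_config():
    """Small optimizer budget for feature-selection unit tests."""
    return FSConfig(optimizer=OptimizerConfig(n_agents=6, n_iterations=15))
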