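import numpy as np
import pytest
from hypothesis import settings

from pigvoc.model import ModelConfig
from pigvoc.synthetic import generate_dataset
from pigvoc.training import dataset_features

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_manifest():
    """A small but structurally complete synthetic dataset (20/class)."""
    return generate_dataset(n_per_class=20, seed=11)


@pytest.fixture(scope="session")
def small_features(small_manifest):
    return dataset_features(small_manifest)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """Small-but-real architecture used by the fast structural tests."""
    return ModelConfig(model_dim=32, front_channels=8, n_heads=2, n_blocks=1,
                       freq_kernel=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
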