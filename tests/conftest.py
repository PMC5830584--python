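import numpy as np
import pytest

from neurocatmap import synth
from scenarios import build_world


@pytest.fixture(scope="session")
def small_config():
    return synth.GeneratorConfig(
        n_layers=6, units_per_layer=(20, 22, 24, 26, 28, 30), n_voxels=150,
        session_length=100, n_train_sessions=3, n_test_sessions=1,
        n_test_repeats=3, noise_sd=1.0, weight_concentration=0.99, seed=5)


@pytest.fixture(scope="session")
def small_hierarchy():
    return synth.CategoryHierarchySpec(categories_per_subgroup=2,
                                       exemplars_per_category_mean=10)


@pytest.fixture(scope="session")
def small_world(small_config, small_hierarchy):
    """One fully processed small synthetic world shared across tests."""
    return build_world(small_config, small_hierarchy)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
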