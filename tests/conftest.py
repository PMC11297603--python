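import numpy as np
import pytest

from mtforestnet.core import ForestParams, MTForestNet
from mtforestnet.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def tiny_params():
    """Small forest for unit tests; the reference 500-tree configuration is
    exercised where the test is specifically about it."""
    return ForestParams(n_estimators=25, random_state=8)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        n_tasks=4,
        chemicals_per_task=120,
        feature_length=64,
        pool_structure="disjoint",
        n_pools=2,
        latent_dim=8,
        task_relatedness=0.9,
        label_noise=0.05,
        positive_fraction=0.35,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_tasks(small_config):
    tasks, _ = generate(small_config)
    return tasks


@pytest.fixture(scope="session")
def fitted_small(small_tasks, tiny_params):
    """A fitted cascade on the small benchmark, shared across tests."""
    return MTForestNet(small_tasks, tiny_params).fit(max_layers=3, split_seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
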