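import numpy as np
import pytest

from traitgpr.models import evaluate_models, fit_trait_models, split_pool
from traitgpr.pools import build_training_pool


@pytest.fixture(scope="session")
def default_pool():
    """The default 2000-sample training pool (1000 simulated + 1000 mixed)."""
    return build_training_pool(seed=0)


@pytest.fixture(scope="session")
def default_split(default_pool):
    return split_pool(default_pool, n_train=250, seed=0)


@pytest.fixture(scope="session")
def trained_models(default_split):
    train, _ = default_split
    return fit_trait_models(train, seed=0)


@pytest.fixture(scope="session")
def eval_report(trained_models, default_split):
    _, val = default_split
    return evaluate_models(trained_models, val)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
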