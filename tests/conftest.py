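import numpy as np
import pytest

from oslom import Config, Graph, gen_lpartition, gen_random


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def triangle():
    return Graph([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture(scope="session")
def er_graph():
    """A mid-size random graph with no community structure."""
    return gen_random("er", 200, avg_k=8.0, seed=7)


@pytest.fixture(scope="session")
def planted():
    """Planted 4-partition with well-separated groups, plus ground truth."""
    return gen_lpartition(128, 4, 12.0, 0.1, seed=11)


@pytest.fixture
def fast_cfg():
    """Small-trial configuration for unit tests."""
    return Config(trials=6, runs=2, null_samples=5_000, seed=5)
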