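import numpy as np
import pytest

from hmdbn import DiscreteTimeSeries, NodeHMMSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240923)


def random_spec(rng, H, T):
    """Random valid NodeHMMSpec for oracle comparisons."""
    pi = rng.dirichlet(np.ones(H))
    A = rng.dirichlet(np.ones(H), size=H)
    B = rng.uniform(0.05, 1.0, size=(H, T))
    return NodeHMMSpec(pi=pi, A=A, B=B)


def random_discrete(rng, n, t1, arity=2):
    values = rng.integers(0, arity, size=(n, t1))
    return DiscreteTimeSeries(values, [f"g{i}" for i in range(n)],
                              [arity] * n)


@pytest.fixture
def spec_factory(rng):
    return lambda H, T: random_spec(rng, H, T)


@pytest.fixture
def data_factory(rng):
    return lambda n, t1, arity=2: random_discrete(rng, n, t1, arity)
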