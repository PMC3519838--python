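import numpy as np
import pytest

from mmkmeans import AlgoConfig, DataMatrix, MixtureSpec, generate_mixture


@pytest.fixture
def small_mixture():
    """A well-separated 300x8 mixture with 4 components and its truth."""
    spec = MixtureSpec(n=300, d=8, k_true=4, separation=10.0, noise_sd=0.5, seed=42)
    return generate_mixture(spec)


@pytest.fixture
def tiny_matrix():
    """A hand-sized matrix: two well-separated 1-D pairs embedded in 2-D."""
    values = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0], [11.0, 0.0]])
    return DataMatrix(ids=["a", "b", "c", "d"], values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_config(k, seed=0, **kw):
    return AlgoConfig(k=k, seed=seed, **kw)
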