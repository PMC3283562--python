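import numpy as np
import pytest

from sparsesca import BlockSpec, MultiBlockMatrix, preprocess


def make_data(seed, n_samples, block_sizes):
    """Seeded preprocessed multi-block Gaussian test matrix."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_samples, int(sum(block_sizes))))
    return preprocess(MultiBlockMatrix(X, BlockSpec.from_sizes(block_sizes)))


def make_correlated_data(seed, n_samples, block_sizes, rank=3, noise=0.3):
    """Low-rank-plus-noise multi-block data (correlated columns)."""
    rng = np.random.default_rng(seed)
    p = int(sum(block_sizes))
    X = rng.normal(size=(n_samples, rank)) @ rng.normal(size=(rank, p))
    X += noise * rng.normal(size=(n_samples, p))
    return preprocess(MultiBlockMatrix(X, BlockSpec.from_sizes(block_sizes)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_data():
    return make_data(7, 20, (4, 3))
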