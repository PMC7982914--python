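import numpy as np
import pytest

from mkfuse.io import FeatureView, LabelSet
from mkfuse.kernels import KernelMatrix
from mkfuse.synthetic import SyntheticConfig, generate


def ids(n, prefix="s"):
    return [f"{prefix}{i:03d}" for i in range(n)]


def random_symmetric(rng, n, scale=1.0):
    A = rng.normal(scale=scale, size=(n, n))
    return (A + A.T) / 2.0


def random_psd(rng, n, rank=None):
    B = rng.normal(size=(n, rank or n))
    return B @ B.T


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_view(rng):
    return FeatureView("gene", ids(8), rng.normal(size=(8, 5)))


@pytest.fixture
def binary_labels():
    return LabelSet(ids(6), ["a", "a", "a", "b", "b", "b"])


@pytest.fixture
def easy_dataset():
    """Well-separated 3-class, 3-view dataset; only view 0 is informative."""
    cfg = SyntheticConfig(
        n_per_class=[20, 20, 20],
        ambient_dims=[80, 80, 80],
        informative_dims=[10, 10, 10],
        separation=[8.0, 0.0, 0.0],
        seed=7,
    )
    return generate(cfg)


def kernel_from(rng_or_mat, ids_list=None, kind="combined"):
    M = rng_or_mat
    if ids_list is None:
        ids_list = ids(M.shape[0], "k")
    return KernelMatrix(ids_list, M, kind)
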