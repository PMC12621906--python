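import numpy as np
import pytest

from sakura.data import ExpressionMatrix


@pytest.fixture(scope="session")
def rare_subtype_benchmark():
    """Full-pipeline benchmark on the rare-subtype fixture, 3 seeds.

    Shared session-wide: trains the knowledge-guided model (normal and
    over-supervised intensity) per seed and clusters/evaluates both it and
    the PCA-50 baseline. Takes a few minutes; every consumer reuses it.
    """
    from sakura.benchmark import run_rare_subtype_benchmark

    return run_rare_subtype_benchmark(seeds=(0, 1, 2))


@pytest.fixture
def toy_raw():
    """Small raw count matrix with known totals."""
    counts = np.array([
        [10.0, 0.0, 10.0],
        [1.0, 2.0, 3.0],
        [0.0, 0.0, 0.0],
        [5.0, 5.0, 0.0],
    ])
    return ExpressionMatrix(counts, layer_tag="raw")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_blob_embedding(rng, n_per=30, sep=20.0, d=5):
    """Two well-separated Gaussian blobs plus labels."""
    a = rng.normal(size=(n_per, d))
    b = rng.normal(size=(n_per, d))
    b[:, 0] += sep
    labels = np.array([0] * n_per + [1] * n_per)
    return np.vstack([a, b]), labels
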