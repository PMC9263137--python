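import numpy as np
import pytest

from kcselect import ExpressionMatrix


def make_blobs(centers, per, scale=0.3, dim=5, seed=0):
    """Well-separated Gaussian blobs; returns (values, 1-based labels)."""
    rng = np.random.default_rng(seed)
    blocks = [rng.normal(c, scale, size=(per, dim)) for c in centers]
    labels = np.repeat(np.arange(1, len(centers) + 1), per)
    return np.vstack(blocks), labels


def as_expression(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionMatrix(
        np.abs(values), [f"c{i}" for i in range(n)], [f"{prefix}{j}" for j in range(p)]
    )


@pytest.fixture
def blobs3():
    return make_blobs((0.0, 5.0, 10.0), per=20, seed=2)
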