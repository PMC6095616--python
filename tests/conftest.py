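import numpy as np
import pytest

from dyncorr.io import ExpressionMatrix, standardize


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_matrix(rng):
    """5 genes x 12 samples of i.i.d. normals, unstandardized."""
    values = rng.standard_normal((5, 12))
    return ExpressionMatrix(
        values,
        tuple(f"g{i}" for i in range(5)),
        tuple(f"s{j}" for j in range(12)),
    )


@pytest.fixture
def std_matrix(toy_matrix):
    return standardize(toy_matrix)


def standardize_vec(a):
    a = np.asarray(a, dtype=float)
    return (a - a.mean()) / a.std(ddof=0)
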