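import numpy as np
import pytest

from mhmnorm import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20140701)


def random_matrix(rng, m=None, n=None, ties=False) -> ExpressionMatrix:
    """Random expression matrix; integer-valued when ties are requested."""
    m = int(rng.integers(2, 21)) if m is None else m
    n = int(rng.integers(2, 11)) if n is None else n
    if ties:
        values = rng.integers(0, 8, size=(m, n)).astype(float)
    else:
        values = rng.uniform(0.0, 100.0, size=(m, n))
    return ExpressionMatrix(values)


@pytest.fixture
def worked_example() -> ExpressionMatrix:
    return ExpressionMatrix(np.array([[1.0, 10.0], [2.0, 3.0]]))
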