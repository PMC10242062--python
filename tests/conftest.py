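import numpy as np
import pytest

from ifpca import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def as_matrix(values: np.ndarray) -> ExpressionMatrix:
    """Wrap a plain array with generated identifiers."""
    n, p = values.shape
    return ExpressionMatrix(
        values,
        [f"s{i}" for i in range(n)],
        [f"g{j}" for j in range(p)],
    )


@pytest.fixture
def small_planted():
    from ifpca import generate_planted_data

    return generate_planted_data(
        n=60, p=80, K=2, n_useful=10, effect_size=2.0, noise_sd=1.0, seed=3
    )
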