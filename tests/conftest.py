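import numpy as np
import pytest

from blockpath import DataBlock, encode_outcome


@pytest.fixture
def rng():
    return np.random.default_rng(20230373)


@pytest.fixture
def small_block():
    """4 samples x 3 variables with one zero entry."""
    values = np.array(
        [
            [0.0, 3.0, 1.0],
            [5.0, 5.0, 2.0],
            [10.0, 10.0, 4.0],
            [2.0, 7.0, 8.0],
        ]
    )
    return DataBlock(
        values=values,
        sample_ids=("s1", "s2", "s3", "s4"),
        variable_ids=("m1", "m2", "m3"),
    )


@pytest.fixture
def binary_outcome():
    return encode_outcome(
        ("s1", "s2", "s3", "s4"),
        ("case", "control", "case", "control"),
        case_label="case",
    )


def regression_problem(rng, n=50, p=5, q=1, noise=0.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=(p, q))
    Y = X @ beta + noise * rng.normal(size=(n, q))
    return X, Y


@pytest.fixture
def ols_oracle():
    """Least-squares predictions via normal equations on centered data."""

    def _fit_predict(X, Y):
        Y = Y if Y.ndim == 2 else Y[:, None]
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ Yc)
        return Xc @ beta + Y.mean(axis=0)

    return _fit_predict
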