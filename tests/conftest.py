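import numpy as np
import pytest

import degratrace as dt


@pytest.fixture(scope="session")
def bbd_table() -> dt.ResponseTable:
    """The 15-run triclosan Box-Behnken experiment."""
    return dt.triclosan_bbd_table()


@pytest.fixture(scope="session")
def full_model(bbd_table) -> dt.QuadraticModel:
    return dt.fit_quadratic(bbd_table)


@pytest.fixture(scope="session")
def pruned_model(bbd_table, full_model) -> dt.QuadraticModel:
    return dt.prune_interactions(full_model, bbd_table, alpha=0.05)


def grid_argmax_2d(coef_fn, step: float = 1e-3):
    """Brute-force argmax of a bivariate function over [-1, 1]^2.

    Independent oracle for the canonical (stationary-point) analysis:
    evaluates the surface on a dense grid and returns the best point and
    value.
    """
    g = np.arange(-1.0, 1.0 + step / 2, step)
    X, Y = np.meshgrid(g, g, indexing="ij")
    Z = coef_fn(X, Y)
    idx = np.unravel_index(np.argmax(Z), Z.shape)
    return np.array([X[idx], Y[idx]]), float(Z[idx])
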