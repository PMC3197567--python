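"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from scipy.integrate import solve_bvp

from tissuetarget import DimensionlessParameters


def random_o1_params(rng, lambda1=0.0):
    """Draw a random O(1) dimensionless parameter set."""
    return DimensionlessParameters(
        lambda1=lambda1,
        lambda2=rng.uniform(0.1, 3.0),
        lambda3=rng.uniform(0.1, 3.0),
        lambda4=rng.uniform(0.1, 3.0),
        lambda5=rng.uniform(0.1, 3.0),
        mu_A=rng.uniform(0.5, 2.0),
        mu_B=rng.uniform(0.5, 2.0),
        delta_A=rng.uniform(0.5, 2.0),
        delta_B=rng.uniform(0.5, 2.0),
    )


def leading_order_oracle(p, x_eval):
    """Independent collocation solve of the leading-order steady system.

    Uses scipy's adaptive collocation (solve_bvp) on the coupled linear
    system, a completely different route from the closed cosh forms:

        delta_A A'' = lambda3 A - lambda2 mu_A C
        delta_B B'' = lambda4 B - lambda5 C
                C'' = lambda2 C

    with zero slope at x = 0 and value 1 at x = 1.
    """

    def fun(x, y):
        A, dA, B, dB, C, dC = y
        return np.vstack(
            [
                dA,
                (p.lambda3 * A - p.lambda2 * p.mu_A * C) / p.delta_A,
                dB,
                (p.lambda4 * B - p.lambda5 * C) / p.delta_B,
                dC,
                p.lambda2 * C,
            ]
        )

    def bc(ya, yb):
        return np.array([ya[1], ya[3], ya[5], yb[0] - 1, yb[2] - 1, yb[4] - 1])

    x0 = np.linspace(0, 1, 101)
    y0 = np.ones((6, x0.size))
    y0[1] = y0[3] = y0[5] = 0.0
    sol = solve_bvp(fun, bc, x0, y0, tol=1e-10, max_nodes=200000)
    assert sol.success, sol.message
    y = sol.sol(x_eval)
    return y[0], y[2], y[4]


@pytest.fixture
def rng():
    return np.random.default_rng(20110922)
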