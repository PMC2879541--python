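"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: quadrature
integrals are taken of the closed-form density, and the brute-force MLE does
a 2-D numerical likelihood maximization at every candidate mode instead of
the closed-form profile solution.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import integrate, optimize

from skewlap import SkewLaplaceParams, sl_pdf


def quad_split(fun, params: SkewLaplaceParams, width: float = 40.0):
    """Adaptive quadrature of ``fun`` over the effective support, split at the mode."""
    lo = params.mu - width / params.alpha
    hi = params.mu + width / params.beta
    left, _ = integrate.quad(fun, lo, params.mu, limit=200)
    right, _ = integrate.quad(fun, params.mu, hi, limit=200)
    return left + right


def numeric_inner_mle(x: np.ndarray, mu: float) -> tuple[float, float, float]:
    """Numerically maximize the likelihood over (alpha, beta) at fixed mu.

    Works on log-rates so the optimizer is unconstrained; returns
    (alpha, beta, loglik).
    """
    n = x.size
    A = float(np.mean(np.clip(mu - x, 0.0, None)))
    B = float(np.mean(np.clip(x - mu, 0.0, None)))

    def neg_ll(theta):
        a, b = np.exp(theta)
        return -n * (np.log(a * b / (a + b)) - a * A - b * B)

    res = optimize.minimize(neg_ll, x0=[0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 20000})
    a, b = np.exp(res.x)
    return float(a), float(b), float(-res.fun)


def brute_force_mle(x: np.ndarray) -> tuple[float, float, float, float]:
    """Exhaustive MLE oracle: numeric 2-D inner maximization at every candidate mode.

    Only candidates with data on both sides are admissible (the one-sided
    limit is degenerate).  Returns (mu, alpha, beta, loglik).
    """
    best = None
    for mu in np.unique(x):
        A = np.mean(np.clip(mu - x, 0.0, None))
        B = np.mean(np.clip(x - mu, 0.0, None))
        if A == 0.0 or B == 0.0:
            continue
        a, b, ll = numeric_inner_mle(x, float(mu))
        if best is None or ll > best[3]:
            best = (float(mu), a, b, ll)
    assert best is not None
    return best


@pytest.fixture(scope="session")
def saureus_ss_params() -> SkewLaplaceParams:
    """Strongly right-skewed side-scatter parameters (cocci at 6 h)."""
    return SkewLaplaceParams(mu=424.0, alpha=0.134, beta=0.009)


@pytest.fixture(scope="session")
def symmetric_params() -> SkewLaplaceParams:
    return SkewLaplaceParams(mu=0.0, alpha=1.0, beta=1.0)
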