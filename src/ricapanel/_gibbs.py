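"""Numba-compiled single-site Gibbs sweeps for whole-genome regression.

The sweeps update marker effects in place against a running residual; all
random draws are supplied by the caller (pre-drawn standard normals and
uniforms), so chains are exactly reproducible from a NumPy generator.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def sweep_dense(X, xtx, e, beta, var_beta, sigma_e2, z):
    """One sweep with every marker in the model (BayesA / ridge-like /
    Bayesian-lasso conditionals).  ``var_beta[j]`` is marker j's current
    prior effect variance."""
    m = beta.shape[0]
    n = e.shape[0]
    for j in range(m):
        xj = X[:, j]
        old = beta[j]
        dot = 0.0
        for i in range(n):
            dot += xj[i] * e[i]
        rhs = dot + xtx[j] * old
        c = xtx[j] + sigma_e2 / var_beta[j]
        new = rhs / c + z[j] * np.sqrt(sigma_e2 / c)
        diff = old - new
        if diff != 0.0:
            for i in range(e.shape[0]):
                e[i] += xj[i] * diff
        beta[j] = new


@njit(cache=False)
def sweep_mixture(X, xtx, e, beta, var_beta, sigma_e2, pi, incl, z, u):
    """One spike-and-slab sweep (BayesB / BayesC conditionals).

    Marker j enters with probability proportional to pi * BayesFactor where
    the Bayes factor integrates the effect out of its conditional normal.
    Returns the number of included markers.
    """
    m = beta.shape[0]
    n = e.shape[0]
    n_in = 0
    for j in range(m):
        xj = X[:, j]
        old = beta[j]
        dot = 0.0
        for i in range(n):
            dot += xj[i] * e[i]
        rhs = dot + xtx[j] * old
        v = var_beta[j]
        c = xtx[j] + sigma_e2 / v
        log_bf = 0.5 * (np.log(sigma_e2) - np.log(v * c)) + rhs * rhs / (2.0 * sigma_e2 * c)
        # guard overflow
        if log_bf > 50.0:
            p_in = 1.0
        else:
            bf = np.exp(log_bf)
            p_in = pi * bf / (pi * bf + (1.0 - pi))
        if u[j] < p_in:
            new = rhs / c + z[j] * np.sqrt(sigma_e2 / c)
            incl[j] = 1
            n_in += 1
        else:
            new = 0.0
            incl[j] = 0
        diff = old - new
        if diff != 0.0:
            for i in range(e.shape[0]):
                e[i] += xj[i] * diff
        beta[j] = new
    return n_in
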