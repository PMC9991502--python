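"""Numba kernels for the single-site spike-slab Gibbs scans.

The marker scan walks markers in the outer loop and factors (or traits) in
the inner loop so each dosage column is streamed once per sweep while the
per-factor residual vectors stay cache-resident.  Residuals are maintained
incrementally: removing a coefficient's contribution is folded into the
right-hand side via ``rhs = x'r + x'x * b_old``.

All kernels draw from numba's own ``np.random`` state, seeded explicitly at
the top of every call, so sweeps are deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["spike_slab_scalar", "marker_scan", "loading_scan"]


@njit(cache=True, inline="always")
def _spike_slab_draw(rhs, xx, sigma2_e, sigma2_b, pi):
    """One conjugate spike-slab draw given sufficient statistics.

    Returns (coefficient, indicator).  ``rhs`` is x'y_res with the current
    coefficient's contribution already restored.  When x'x == 0 the slab and
    spike marginal likelihoods coincide and the indicator follows prior odds.
    """
    if pi >= 1.0:
        return 0.0, 0
    v = xx / sigma2_e + 1.0 / sigma2_b  # posterior precision
    mu = rhs / (sigma2_e * v)
    # log marginal-likelihood ratio slab/spike
    log_bf = 0.5 * mu * mu * v - 0.5 * np.log(sigma2_b * v)
    if pi <= 0.0:
        include = True
    else:
        log_odds = np.log((1.0 - pi) / pi) + log_bf
        # sample indicator from its Bernoulli full conditional
        u = np.random.random()
        include = np.log(u / (1.0 - u)) < log_odds
    if include:
        return mu + np.random.normal() / np.sqrt(v), 1
    return 0.0, 0


@njit(cache=True)
def spike_slab_scalar(y_res, x, sigma2_e, sigma2_b, pi, seed):
    """Single-coefficient spike-slab update (library entry point)."""
    np.random.seed(seed)
    xx = 0.0
    rhs = 0.0
    for i in range(x.shape[0]):
        xx += x[i] * x[i]
        rhs += x[i] * y_res[i]
    return _spike_slab_draw(rhs, xx, sigma2_e, sigma2_b, pi)


@njit(cache=True, fastmath=True)
def marker_scan(X, xtx, Rt, B, incl, sigma2_e, sigma2_b, pi, seed):
    """One systematic scan of marker effects for K factors (or traits).

    Parameters
    ----------
    X : (n, p) float64, Fortran-contiguous dosage/covariate matrix.
    xtx : (p,) precomputed column sums of squares.
    Rt : (K, n) residuals, one row per factor; updated in place.
    B : (p, K) coefficients, updated in place.
    incl : (p, K) int8 inclusion indicators, updated in place.
    sigma2_e, sigma2_b, pi : (K,) per-factor residual variance, slab
        variance and exclusion probability.
    """
    np.random.seed(seed)
    n, p = X.shape
    K = Rt.shape[0]
    for j in range(p):
        xj = X[:, j]
        xx = xtx[j]
        for k in range(K):
            b_old = B[j, k]
            r = Rt[k]
            rhs = 0.0
            for i in range(n):
                rhs += xj[i] * r[i]
            rhs += xx * b_old
            b_new, ind = _spike_slab_draw(rhs, xx, sigma2_e[k], sigma2_b[k], pi[k])
            B[j, k] = b_new
            incl[j, k] = ind
            d = b_new - b_old
            if d != 0.0:
                for i in range(n):
                    r[i] -= d * xj[i]


@njit(cache=True, fastmath=True)
def loading_scan(F, ftf, RYt, Lam, incl, fixed_mask, tau, sigma2_R, pi_lambda, seed):
    """One systematic scan of the K x t loading matrix.

    The slab variance of lambda_{kj} is sigma2_R[j] / tau[k]; the residual
    variance is sigma2_R[j]; the exclusion probability pi_lambda[k] is shared
    across a factor's row.  Entries with fixed_mask set are skipped.
    ``RYt`` is (t, n): per-trait residual y_j - X1 b1_j - F lambda_j.
    """
    np.random.seed(seed)
    n = F.shape[0]
    K, t = Lam.shape
    for j in range(t):
        r = RYt[j]
        s2e = sigma2_R[j]
        for k in range(K):
            if fixed_mask[k, j]:
                continue
            lam_old = Lam[k, j]
            fk = F[:, k]
            rhs = 0.0
            for i in range(n):
                rhs += fk[i] * r[i]
            rhs += ftf[k] * lam_old
            s2b = s2e / tau[k]
            lam_new, ind = _spike_slab_draw(rhs, ftf[k], s2e, s2b, pi_lambda[k])
            Lam[k, j] = lam_new
            incl[k, j] = ind
            d = lam_new - lam_old
            if d != 0.0:
                for i in range(n):
                    r[i] -= d * fk[i]
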