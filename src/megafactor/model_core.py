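"""Sparse latent-factor whole-genome regression with spike-slab priors.

The model decomposes an n x t trait matrix as

    Y = F Lambda + X1 B1 (+ X2R B2R) + E_R,      F = X2F B2F + E_F

where F holds K latent factors, Lambda is a sparse K x t loading matrix, and
B2F are marker effects driving the factors.  Marker effects and loadings
carry BayesC mixture priors (point mass at zero with exclusion probability
pi, normal slab otherwise); loadings additionally receive a multiplicative
gamma shrinkage prior on their row-wise precision:

    lambda_kj ~ (1 - pi_Lambda_k) N(0, sigma2_Rj / tau_k) + pi_Lambda_k d0
    tau_k = prod_{h<=k} delta_h,   delta_1 = 1,  delta_h ~ Gamma(a_d, b_d)

so later factor rows are shrunk increasingly hard toward zero.  For
identifiability the factor residual variance is fixed at 1 wherever the
loading row is free (scale is absorbed by Lambda); rows fully pinned by a
fixed-loading pattern carry a sampled residual variance instead, since the
pinned scale makes it identifiable.  Inference is by a systematic-scan
Gibbs sampler with single-site updates for B2F and Lambda.

Two variants are provided: ``megabayesc`` (all pi's estimated) and
``megarrblup`` (marker exclusion probabilities pinned to 0 so every marker
is included, the ridge / RR-BLUP limit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from ._kernels import loading_scan, marker_scan, spike_slab_scalar

__all__ = [
    "Hyperparameters",
    "ModelData",
    "FactorModelState",
    "PosteriorChain",
    "fixed_first_factor_spec",
    "initialize_state",
    "spike_slab_update",
    "gibbs_sweep",
    "run_mcmc",
    "focal_marker_effects",
    "focal_marker_effect_sd",
    "predict_genetic_values",
    "genetic_variance_samples",
]


@dataclass
class Hyperparameters:
    """Prior settings for the factor model.

    Defaults: a stochastically increasing shrinkage ladder
    (delta_h ~ Gamma(2, 1), so E[tau_k] = 2^(k-1)), Inv-Gamma(1, 1) on the
    trait residual variances, Beta(1, 1) on every exclusion probability, and
    a scaled-Inv-chi2(df=4) prior on the marker-effect variances whose scale
    is matched at initialization to place half the target variance on the
    expected number of included markers.
    """

    n_factors: int = 10
    a_delta: float = 2.0
    b_delta: float = 1.0
    a_sigma: float = 1.0
    b_sigma: float = 1.0
    pi_lambda_beta: tuple[float, float] = (1.0, 1.0)
    pi_f_beta: tuple[float, float] = (1.0, 1.0)
    pi_r_beta: tuple[float, float] = (1.0, 1.0)
    marker_var_df: float = 4.0
    marker_var_scale: float | None = None  # per-factor slab scale; matched if None
    fixed_loadings: tuple[np.ndarray, np.ndarray] | None = None  # (mask K x t, values)

    def __post_init__(self) -> None:
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        for name in ("a_delta", "b_delta", "a_sigma", "b_sigma", "marker_var_df"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def fixed_first_factor_spec(K: int, t: int, focal_index: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Pin the first factor's loadings to the focal-trait unit vector.

    Row 1 of Lambda becomes (0, ..., 1, ..., 0) with the 1 at the focal
    trait, so the first column of B2F models marker effects acting directly
    and exclusively on the focal trait.
    """
    mask = np.zeros((K, t), dtype=bool)
    values = np.zeros((K, t))
    mask[0, :] = True
    values[0, focal_index] = 1.0
    return mask, values


@dataclass
class ModelData:
    """Observed data and design matrices for one model fit."""

    Y: np.ndarray  # (n, t), NaN = missing/masked
    X2F: np.ndarray  # (n, p) genotype covariates driving the factors
    X1: np.ndarray | None = None  # (n, b1) fixed effects; default intercept
    X2R: np.ndarray | None = None  # optional trait-specific marker design
    focal_index: int = 0

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be 2-D (samples x traits)")
        if np.isinf(self.Y).any():
            raise ValueError("non-finite Y entries outside the missing mask")
        self.X2F = np.asfortranarray(np.asarray(self.X2F, dtype=float))
        if self.X1 is None:
            self.X1 = np.ones((self.Y.shape[0], 1))
        self.X1 = np.asarray(self.X1, dtype=float)
        if self.X2R is not None:
            self.X2R = np.asfortranarray(np.asarray(self.X2R, dtype=float))
        n = self.Y.shape[0]
        if self.X2F.shape[0] != n or self.X1.shape[0] != n:
            raise ValueError("design matrix rows do not match Y")
        if not (0 <= self.focal_index < self.Y.shape[1]):
            raise ValueError("focal_index out of range")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.Y)


@dataclass
class FactorModelState:
    """One MCMC state of the factor model (all arrays mutated in place)."""

    F: np.ndarray
    Lambda: np.ndarray
    lambda_incl: np.ndarray
    B1: np.ndarray
    B2F: np.ndarray
    b2f_incl: np.ndarray
    sigma2_R: np.ndarray
    sigma2_B2F: np.ndarray
    sigma2_F: np.ndarray  # factor residual variance: 1 for free rows, sampled for pinned rows
    delta: np.ndarray
    tau: np.ndarray
    pi_lambda: np.ndarray
    pi_f: np.ndarray
    Ycur: np.ndarray  # Y with missing entries imputed
    rng: np.random.Generator
    fixed_mask: np.ndarray
    iteration: int = 0
    # optional trait-specific marker effects
    B2R: np.ndarray | None = None
    b2r_incl: np.ndarray | None = None
    sigma2_B2R: np.ndarray | None = None
    pi_r: np.ndarray | None = None
    # cached design products, kept consistent by gibbs_sweep
    XB: np.ndarray | None = None  # X2F @ B2F
    XRB: np.ndarray | None = None  # X2R @ B2R
    log_joint: float = np.nan


@dataclass
class PosteriorChain:
    """Thinned post-burn-in draws and summaries of the quantities of interest."""

    alpha_sum: np.ndarray  # running sum of per-draw B2F @ lambda_focal
    alpha_sq_sum: np.ndarray
    alpha_draws: np.ndarray | None  # (n_draws, p) float32, optional
    gvar_draws: np.ndarray  # per-draw var across individuals of X2F B2F lambda_f
    Lambda_draws: np.ndarray  # (n_draws, K, t) float32
    pi_lambda_draws: np.ndarray
    pi_f_draws: np.ndarray
    sigma2_R_mean: np.ndarray
    sigma2_F_mean: np.ndarray
    sigma2_B2F_mean: np.ndarray
    log_joint: np.ndarray  # per recorded iteration
    n_iter: int
    burnin: int
    thin: int
    seed: int
    variant: str
    focal_index: int
    n_samples_data: int

    @property
    def n_draws(self) -> int:
        return len(self.gvar_draws)


# ---------------------------------------------------------------------------


def slab_posterior(y_res, x, sigma2_e, sigma2_b) -> tuple[float, float, float]:
    """Closed-form conjugate slab posterior for one coefficient.

    Returns (posterior mean, posterior variance, log marginal-likelihood
    ratio of slab vs spike).  The posterior mean equals the ridge solution
    x'y / (x'x + sigma2_e / sigma2_b).
    """
    x = np.asarray(x, dtype=float)
    y_res = np.asarray(y_res, dtype=float)
    xx = float(x @ x)
    rhs = float(x @ y_res)
    v = xx / sigma2_e + 1.0 / sigma2_b
    mean = rhs / (sigma2_e * v)
    log_bf = 0.5 * mean * mean * v - 0.5 * np.log(sigma2_b * v)
    return mean, 1.0 / v, log_bf


def spike_slab_update(y_res, x, sigma2_e, sigma2_b, pi, rng) -> tuple[float, int]:
    """Sample one coefficient from its conjugate spike-slab full conditional.

    The indicator is drawn from its Bernoulli conditional (slab vs spike
    marginal-likelihood ratio); if included, the coefficient comes from the
    conjugate normal; if excluded it is exactly 0.  A zero-variance ``x``
    makes the two marginal likelihoods equal, so the indicator follows the
    prior odds.
    """
    if not (sigma2_e > 0 and sigma2_b > 0):
        raise ValueError("variances must be positive")
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    seed = int(rng.integers(2**31)) if isinstance(rng, np.random.Generator) else int(rng)
    b, ind = spike_slab_scalar(
        np.ascontiguousarray(y_res, dtype=float),
        np.ascontiguousarray(x, dtype=float),
        float(sigma2_e),
        float(sigma2_b),
        float(pi),
        seed,
    )
    return float(b), int(ind)


def initialize_state(data: ModelData, hyper: Hyperparameters, seed: int) -> FactorModelState:
    """Deterministic-given-seed start point for the Gibbs sampler.

    F and Lambda come from a truncated rank-K SVD of the column-standardized
    observed Y (missing cells mean-filled for the decomposition only, zero
    for all-missing columns); coefficients start at zero, variances at their
    prior means, inclusion indicators are drawn from the prior pi's, and any
    fixed-loading pattern is applied on top.
    """
    rng = np.random.default_rng(seed)
    Y = data.Y
    n, t = Y.shape
    K = hyper.n_factors
    if K > min(n, t):
        raise ValueError(f"K={K} exceeds min(n, t)={min(n, t)}")
    p = data.X2F.shape[1]

    miss = data.missing_mask
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(Y, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    Yfill = np.where(miss, col_mean, Y)
    sd = Yfill.std(axis=0)
    sd[sd == 0] = 1.0
    Ystd = (Yfill - Yfill.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Ystd, full_matrices=False)
    F = U[:, :K] * np.sqrt(n)
    Lam = (S[:K, None] * Vt[:K]) / np.sqrt(n) * sd  # back on the Y scale

    fixed_mask = np.zeros((K, t), dtype=bool)
    if hyper.fixed_loadings is not None:
        fm, fv = hyper.fixed_loadings
        fm = np.asarray(fm, dtype=bool)
        if fm.shape != (K, t):
            raise ValueError("fixed_loadings mask must be K x t")
        fixed_mask = fm
        Lam = np.where(fixed_mask, np.asarray(fv, dtype=float), Lam)

    a_pl, b_pl = hyper.pi_lambda_beta
    a_pf, b_pf = hyper.pi_f_beta
    pi_lambda = np.full(K, a_pl / (a_pl + b_pl))
    pi_f = np.full(K, a_pf / (a_pf + b_pf))
    lambda_incl = (rng.random((K, t)) > pi_lambda[:, None]).astype(np.int8)
    lambda_incl[fixed_mask] = 1
    # keep the SVD start consistent with the indicator invariant
    Lam = np.where((lambda_incl == 0) & ~fixed_mask, 0.0, Lam)
    b2f_incl = (rng.random((p, K)) > pi_f[None, :]).astype(np.int8)

    sigma2_R = np.full(t, hyper.b_sigma / max(hyper.a_sigma - 1.0, 0.5))  # prior mean-ish
    # factor residual variances: 1 where the loading row is free (scale lives in
    # Lambda); sampled where the row is fully pinned, since the pinned scale
    # makes the factor variance identifiable
    fixed_row = fixed_mask.all(axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        var_y = np.nanvar(Y, axis=0)
    var_y = np.maximum(np.where(np.isnan(var_y), 1.0, var_y), 1e-8)
    row_target = np.ones(K)  # variance scale each factor must carry
    if fixed_row.any():
        lam_fixed = np.where(fixed_mask, Lam, 0.0)
        row_target[fixed_row] = np.maximum((lam_fixed[fixed_row] ** 2) @ var_y, 1e-8)
    sigma2_F = np.ones(K)
    sigma2_F[fixed_row] = np.maximum(0.5 * row_target[fixed_row], 1e-6)
    mean_xtx = float(np.mean(np.sum(data.X2F**2, axis=0)) / n)
    expected_incl = max(p * (1.0 - pi_f.mean()), 1.0)
    if hyper.marker_var_scale is None:
        scale = 0.5 * row_target / max(mean_xtx * expected_incl, 1e-12)
    else:
        scale = np.full(K, hyper.marker_var_scale)
    nu = hyper.marker_var_df
    sigma2_B2F = nu * scale / max(nu - 2.0, 0.5)

    delta = np.ones(K)
    if K > 1:
        delta[1:] = hyper.a_delta / hyper.b_delta  # prior mean
    tau = np.cumprod(delta)

    Ycur = Yfill.copy()
    state = FactorModelState(
        F=F,
        Lambda=Lam,
        lambda_incl=lambda_incl,
        B1=np.zeros((data.X1.shape[1], t)),
        B2F=np.zeros((p, K)),
        b2f_incl=b2f_incl,
        sigma2_R=sigma2_R,
        sigma2_B2F=sigma2_B2F,
        sigma2_F=sigma2_F,
        delta=delta,
        tau=tau,
        pi_lambda=pi_lambda,
        pi_f=pi_f,
        Ycur=Ycur,
        rng=rng,
        fixed_mask=fixed_mask,
    )
    if data.X2R is not None:
        b2r_n = data.X2R.shape[1]
        a_pr, b_pr = hyper.pi_r_beta
        state.pi_r = np.full(t, a_pr / (a_pr + b_pr))
        state.b2r_incl = (rng.random((b2r_n, t)) > state.pi_r[None, :]).astype(np.int8)
        state.B2R = np.zeros((b2r_n, t))
        mean_xtx_r = float(np.mean(np.sum(data.X2R**2, axis=0)) / n)
        scale_r = 0.5 * var_y / np.maximum(mean_xtx_r * b2r_n * (1.0 - state.pi_r), 1e-12)
        state.sigma2_B2R = nu * scale_r / max(nu - 2.0, 0.5)
    state.XB = data.X2F @ state.B2F
    state.XRB = None if data.X2R is None else data.X2R @ state.B2R
    state._scale_B2F = scale  # stash for the variance update
    return state


def _sample_scaled_inv_chi2(rng, df: float, scale: float, m: int, ss: float) -> float:
    """Posterior draw of a variance under a scaled-Inv-chi2(df, scale) prior."""
    shape = df + m
    rate = df * scale + ss
    return rate / rng.chisquare(shape)


def gibbs_sweep(
    state: FactorModelState,
    data: ModelData,
    hyper: Hyperparameters,
    variant: str = "megabayesc",
) -> FactorModelState:
    """One full systematic Gibbs scan, mutating ``state`` in place.

    Update order: B1; Lambda (spike-slab); pi_Lambda; delta/tau; F rows;
    B2F (spike-slab, marker by marker); sigma2_B2F and pi_F; optional B2R
    block; sigma2_R; missing-Y imputation.
    """
    rng = state.rng
    X1, X2F, X2R = data.X1, data.X2F, data.X2R
    n, t = data.Y.shape
    K = hyper.n_factors
    p = X2F.shape[1]
    miss = data.missing_mask
    rrblup = variant == "megarrblup"

    XRB = state.XRB if state.XRB is not None else 0.0

    # (a) fixed effects, flat prior
    A = X1.T @ X1
    A_inv = np.linalg.inv(A)
    L_Ainv = np.linalg.cholesky(A_inv)
    resid = state.Ycur - state.F @ state.Lambda - XRB
    Bhat = A_inv @ (X1.T @ resid)
    Z = rng.standard_normal(state.B1.shape)
    state.B1 = Bhat + (L_Ainv @ Z) * np.sqrt(state.sigma2_R)[None, :]
    X1B1 = X1 @ state.B1

    # (b) factor loadings, single-site spike-slab with slab var sigma2_Rj / tau_k
    RYt = np.ascontiguousarray((state.Ycur - X1B1 - XRB - state.F @ state.Lambda).T)
    ftf = np.sum(state.F**2, axis=0)
    Fm = np.asfortranarray(state.F)
    loading_scan(
        Fm,
        ftf,
        RYt,
        state.Lambda,
        state.lambda_incl,
        state.fixed_mask,
        state.tau,
        state.sigma2_R,
        state.pi_lambda,
        int(rng.integers(2**31)),
    )

    # (c) pi_Lambda from Beta conditionals on row inclusion counts (free entries)
    a_pl, b_pl = hyper.pi_lambda_beta
    free = ~state.fixed_mask
    n_free = free.sum(axis=1)
    n_incl = (state.lambda_incl.astype(bool) & free).sum(axis=1)
    state.pi_lambda = rng.beta(a_pl + n_free - n_incl, b_pl + n_incl)

    # (d) multiplicative gamma shrinkage: delta_h, h >= 2, sequentially
    incl_free = state.lambda_incl.astype(bool) & free
    z_rows = np.where(incl_free, state.Lambda**2, 0.0) / state.sigma2_R[None, :]
    z_rows = z_rows.sum(axis=1)  # sum_j lambda_kj^2 / sigma2_Rj over included
    m_rows = incl_free.sum(axis=1).astype(float)
    for h in range(1, K):
        tau_wo_h = np.cumprod(state.delta) / state.delta[h]
        shape = hyper.a_delta + 0.5 * m_rows[h:].sum()
        rate = hyper.b_delta + 0.5 * np.sum(tau_wo_h[h:] * z_rows[h:])
        state.delta[h] = rng.gamma(shape, 1.0 / rate)
    state.tau = np.cumprod(state.delta)

    # (e) factor scores, joint normal conditional per row (shared precision)
    Yres = state.Ycur - X1B1 - XRB
    LamD = state.Lambda / state.sigma2_R[None, :]
    M = LamD @ state.Lambda.T + np.diag(1.0 / state.sigma2_F)
    Lc = np.linalg.cholesky(M)
    RHS = Yres @ LamD.T + state.XB / state.sigma2_F[None, :]
    mu = sla.cho_solve((Lc, True), RHS.T).T
    Zf = rng.standard_normal((n, K))
    state.F = mu + sla.solve_triangular(Lc, Zf.T, lower=True, trans="T").T

    # (f) marker effects of the factors, marker-by-marker spike-slab
    RFt = np.ascontiguousarray((state.F - state.XB).T)
    xtx = np.sum(X2F**2, axis=0)
    pi_vec = np.zeros(K) if rrblup else state.pi_f
    marker_scan(
        X2F,
        xtx,
        RFt,
        state.B2F,
        state.b2f_incl,
        state.sigma2_F,
        state.sigma2_B2F,
        pi_vec,
        int(rng.integers(2**31)),
    )
    state.XB = state.F - RFt.T

    # (g) marker-effect variances and inclusion probabilities per factor;
    # pinned-row factors also refresh their residual variance
    m_k = state.b2f_incl.sum(axis=0).astype(float)
    ss_k = np.sum(state.B2F**2, axis=0)
    nu = hyper.marker_var_df
    scale_vec = getattr(state, "_scale_B2F", None)
    if scale_vec is None:
        scale_vec = np.full(K, hyper.marker_var_scale or 1.0)
    for k in range(K):
        state.sigma2_B2F[k] = _sample_scaled_inv_chi2(
            rng, nu, float(scale_vec[k]), int(m_k[k]), ss_k[k]
        )
    fixed_row = state.fixed_mask.all(axis=1)
    if fixed_row.any():
        ss_f = np.sum(RFt**2, axis=1)
        for k in np.where(fixed_row)[0]:
            state.sigma2_F[k] = (hyper.b_sigma + 0.5 * ss_f[k]) / rng.gamma(
                hyper.a_sigma + 0.5 * n, 1.0
            )
    if rrblup:
        state.pi_f[:] = 0.0
    else:
        a_pf, b_pf = hyper.pi_f_beta
        state.pi_f = rng.beta(a_pf + p - m_k, b_pf + m_k)

    # (h) optional trait-specific marker effects
    if X2R is not None:
        RY2 = np.ascontiguousarray((state.Ycur - X1B1 - state.F @ state.Lambda - XRB).T)
        xtx_r = np.sum(X2R**2, axis=0)
        marker_scan(
            X2R,
            xtx_r,
            RY2,
            state.B2R,
            state.b2r_incl,
            state.sigma2_R,
            state.sigma2_B2R,
            state.pi_r,
            int(rng.integers(2**31)),
        )
        state.XRB = state.Ycur - X1B1 - state.F @ state.Lambda - RY2.T
        XRB = state.XRB
        m_j = state.b2r_incl.sum(axis=0).astype(float)
        ss_j = np.sum(state.B2R**2, axis=0)
        b2r = X2R.shape[1]
        var_y = np.maximum(np.nanvar(data.Y, axis=0), 1e-8)
        scale_j = 0.5 * var_y / max(float(np.mean(xtx_r) / n) * b2r * 0.5, 1e-12)
        for j in range(t):
            state.sigma2_B2R[j] = _sample_scaled_inv_chi2(rng, nu, scale_j[j], int(m_j[j]), ss_j[j])
        a_pr, b_pr = hyper.pi_r_beta
        state.pi_r = rng.beta(a_pr + b2r - m_j, b_pr + m_j)
        resid_final = RY2.T
    else:
        resid_final = state.Ycur - X1B1 - state.F @ state.Lambda

    # (i) trait residual variances; loadings contribute through their slab
    ss = np.sum(resid_final**2, axis=0)
    incl_free = state.lambda_incl.astype(bool) & ~state.fixed_mask
    lam_term = np.sum(np.where(incl_free, state.Lambda**2, 0.0) * state.tau[:, None], axis=0)
    m_lam = incl_free.sum(axis=0).astype(float)
    shape = hyper.a_sigma + 0.5 * n + 0.5 * m_lam
    rate = hyper.b_sigma + 0.5 * ss + 0.5 * lam_term
    state.sigma2_R = rate / rng.gamma(shape, 1.0)

    # (j) impute missing / masked Y entries from their predictive normal
    if miss.any():
        mean = X1B1 + state.F @ state.Lambda + (XRB if X2R is not None else 0.0)
        noise = rng.standard_normal(mean.shape) * np.sqrt(state.sigma2_R)[None, :]
        state.Ycur[miss] = (mean + noise)[miss]

    # per-iteration log joint (main density terms); finiteness is the invariant
    ll_y = -0.5 * np.sum(n * np.log(state.sigma2_R) + ss / state.sigma2_R)
    ll_f = -0.5 * np.sum(
        n * np.log(state.sigma2_F)
        + np.sum((state.F - state.XB) ** 2, axis=0) / state.sigma2_F
    )
    lp_b = -0.5 * np.sum(
        np.where(state.b2f_incl.astype(bool), state.B2F**2, 0.0) / state.sigma2_B2F[None, :]
    )
    state.log_joint = ll_y + ll_f + lp_b
    if not np.isfinite(state.log_joint):
        raise FloatingPointError(
            f"non-finite log joint at iteration {state.iteration}"
        )
    state.iteration += 1
    return state


def run_mcmc(
    data: ModelData,
    hyper: Hyperparameters,
    n_iter: int = 10_000,
    burnin: int = 2_000,
    thin: int = 2,
    seed: int = 0,
    variant: str = "megabayesc",
    store_alpha_draws: bool = True,
) -> PosteriorChain:
    """Run the Gibbs sampler and collect thinned post-burn-in draws.

    The stored draw count is floor((n_iter - burnin) / thin).  The focal
    quantities (alpha_f = B2F lambda_f, its X2F image and the genetic
    variance of the focal trait) are computed per draw, never from products
    of posterior means.
    """
    if variant not in ("megabayesc", "megarrblup"):
        raise ValueError(f"unknown variant {variant!r}")
    if not (0 <= burnin < n_iter):
        raise ValueError("need 0 <= burnin < n_iter")
    if thin < 1:
        raise ValueError("thin must be >= 1")

    state = initialize_state(data, hyper, seed)
    if variant == "megarrblup":
        state.pi_f[:] = 0.0
        state.b2f_incl[:] = 1

    n, t = data.Y.shape
    K = hyper.n_factors
    p = data.X2F.shape[1]
    n_draws = (n_iter - burnin) // thin
    lam_f = None

    alpha_sum = np.zeros(p)
    alpha_sq = np.zeros(p)
    alpha_draws = np.empty((n_draws, p), dtype=np.float32) if store_alpha_draws else None
    gvar = np.empty(n_draws)
    Lambda_draws = np.empty((n_draws, K, t), dtype=np.float32)
    pi_l_draws = np.empty((n_draws, K))
    pi_f_draws = np.empty((n_draws, K))
    s2R_sum = np.zeros(t)
    s2F_sum = np.zeros(K)
    s2B_sum = np.zeros(K)
    log_joint = np.empty(n_iter)

    d = 0
    for it in range(n_iter):
        gibbs_sweep(state, data, hyper, variant)
        log_joint[it] = state.log_joint
        if it >= burnin and (it - burnin) % thin == 0 and d < n_draws:
            lam_f = state.Lambda[:, data.focal_index]
            alpha = state.B2F @ lam_f
            alpha_sum += alpha
            alpha_sq += alpha**2
            if alpha_draws is not None:
                alpha_draws[d] = alpha
            g = data.X2F @ alpha
            gvar[d] = np.var(g)
            Lambda_draws[d] = state.Lambda
            pi_l_draws[d] = state.pi_lambda
            pi_f_draws[d] = state.pi_f
            s2R_sum += state.sigma2_R
            s2F_sum += state.sigma2_F
            s2B_sum += state.sigma2_B2F
            d += 1

    return PosteriorChain(
        alpha_sum=alpha_sum,
        alpha_sq_sum=alpha_sq,
        alpha_draws=alpha_draws,
        gvar_draws=gvar,
        Lambda_draws=Lambda_draws,
        pi_lambda_draws=pi_l_draws,
        pi_f_draws=pi_f_draws,
        sigma2_R_mean=s2R_sum / max(d, 1),
        sigma2_F_mean=s2F_sum / max(d, 1),
        sigma2_B2F_mean=s2B_sum / max(d, 1),
        log_joint=log_joint,
        n_iter=n_iter,
        burnin=burnin,
        thin=thin,
        seed=seed,
        variant=variant,
        focal_index=data.focal_index,
        n_samples_data=n,
    )


def focal_marker_effects(chain: PosteriorChain) -> np.ndarray:
    """Posterior mean of the per-draw products B2F lambda_f (alpha_f)."""
    return chain.alpha_sum / max(chain.n_draws, 1)


def focal_marker_effect_sd(chain: PosteriorChain) -> np.ndarray:
    """Posterior standard deviation of alpha_f, from running moments."""
    m = chain.n_draws
    mean = chain.alpha_sum / max(m, 1)
    var = chain.alpha_sq_sum / max(m, 1) - mean**2
    return np.sqrt(np.maximum(var, 0.0))


def predict_genetic_values(chain: PosteriorChain, X2F: np.ndarray) -> np.ndarray:
    """Posterior-mean genetic values u = X2F alpha_f for every individual."""
    X2F = np.asarray(X2F, dtype=float)
    if X2F.shape[1] != len(chain.alpha_sum):
        raise ValueError(
            f"X2F has {X2F.shape[1]} markers, chain has {len(chain.alpha_sum)}"
        )
    return X2F @ focal_marker_effects(chain)


def genetic_variance_samples(chain: PosteriorChain, X2F: np.ndarray) -> np.ndarray:
    """Per-draw empirical variance across individuals of X2F B2F lambda_f."""
    X2F = np.asarray(X2F, dtype=float)
    if X2F.shape[1] != len(chain.alpha_sum):
        raise ValueError("marker mismatch between chain and X2F")
    if chain.alpha_draws is not None:
        g = X2F @ chain.alpha_draws.astype(float).T
        return np.var(g, axis=0)
    if X2F.shape[0] != chain.n_samples_data:
        raise ValueError("chain stores no alpha draws; X2F must match the fitted data")
    return chain.gvar_draws.copy()
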