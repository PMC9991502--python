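"""Single-trait baselines: univariate BayesC and a single-marker scan.

``st_bayesc_fit`` is the one-trait spike-slab whole-genome regression that
the factor model reduces to when secondary traits are ignored.  It shares
the same single-site Gibbs kernel as the factor model.

``gwas_scan`` is the per-marker association scan used as stage 1 of the
two-stage pipeline: ordinary least squares with intercept and covariates
(``ols``), or the same Wald test with a VanRaden-GRM polygenic random effect
whose variance components are estimated once on the null model (``mlm``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._kernels import marker_scan
from .io_formats import GenotypeMatrix

__all__ = ["SingleTraitChain", "st_bayesc_fit", "gwas_scan"]


@dataclass
class SingleTraitChain:
    """Thinned draws and summaries from a univariate BayesC fit."""

    effect_sum: np.ndarray
    effect_sq_sum: np.ndarray
    effect_draws: np.ndarray | None
    pi_draws: np.ndarray
    sigma2_b_draws: np.ndarray
    sigma2_e_draws: np.ndarray
    n_iter: int
    burnin: int
    thin: int
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.pi_draws)

    @property
    def effects(self) -> np.ndarray:
        return self.effect_sum / max(self.n_draws, 1)

    @property
    def effect_sd(self) -> np.ndarray:
        m = max(self.n_draws, 1)
        mean = self.effect_sum / m
        return np.sqrt(np.maximum(self.effect_sq_sum / m - mean**2, 0.0))


def st_bayesc_fit(
    y: np.ndarray,
    X: np.ndarray,
    n_iter: int = 5_000,
    burnin: int = 1_000,
    thin: int = 2,
    seed: int = 0,
    pi_fixed: float | None = None,
    pi_beta: tuple[float, float] = (1.0, 1.0),
    var_df: float = 4.0,
    store_draws: bool = False,
) -> SingleTraitChain:
    """Univariate BayesC: y = mu + X b + e with a spike-slab prior on b.

    Rows with missing y are dropped.  pi (the exclusion probability), the
    slab variance and the residual variance are all sampled unless
    ``pi_fixed`` pins pi.  Returns posterior-mean effects and draws.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    keep = ~np.isnan(y)
    y, X = y[keep], X[keep]
    n, p = X.shape
    if np.var(y) == 0:
        raise ValueError("phenotype is constant; nothing to fit")

    rng = np.random.default_rng(seed)
    Xf = np.asfortranarray(X)
    xtx = np.sum(Xf**2, axis=0)
    mean_xtx = float(xtx.mean() / n)
    var_y = float(np.var(y))

    pi = 0.5 if pi_fixed is None else float(pi_fixed)
    scale_e = 0.5 * var_y
    scale_b = 0.5 * var_y / max(mean_xtx * p * 0.5, 1e-12)
    sigma2_e = var_y
    sigma2_b = var_df * scale_b / (var_df - 2.0)

    b = np.zeros((p, 1))
    incl = np.zeros((p, 1), dtype=np.int8)
    mu = float(y.mean())
    r = np.ascontiguousarray((y - mu)[None, :])  # (1, n) residual

    n_draws = (n_iter - burnin) // thin
    eff_sum = np.zeros(p)
    eff_sq = np.zeros(p)
    draws = np.empty((n_draws, p), dtype=np.float32) if store_draws else None
    pi_draws = np.empty(n_draws)
    s2b_draws = np.empty(n_draws)
    s2e_draws = np.empty(n_draws)
    a_pi, b_pi = pi_beta

    d = 0
    for it in range(n_iter):
        # intercept (flat prior)
        r[0] += mu
        mu = float(r[0].mean()) + rng.standard_normal() * np.sqrt(sigma2_e / n)
        r[0] -= mu
        # marker effects
        marker_scan(
            Xf,
            xtx,
            r,
            b,
            incl,
            np.array([sigma2_e]),
            np.array([sigma2_b]),
            np.array([pi]),
            int(rng.integers(2**31)),
        )
        m = int(incl.sum())
        # slab variance: scaled-Inv-chi2(var_df, scale_b) prior
        sigma2_b = (var_df * scale_b + float(np.sum(b**2))) / rng.chisquare(var_df + m)
        # residual variance
        sigma2_e = (var_df * scale_e + float(np.sum(r**2))) / rng.chisquare(var_df + n)
        if pi_fixed is None:
            pi = float(rng.beta(a_pi + p - m, b_pi + m))
        if it >= burnin and (it - burnin) % thin == 0 and d < n_draws:
            eff_sum += b[:, 0]
            eff_sq += b[:, 0] ** 2
            if draws is not None:
                draws[d] = b[:, 0]
            pi_draws[d] = pi
            s2b_draws[d] = sigma2_b
            s2e_draws[d] = sigma2_e
            d += 1

    return SingleTraitChain(
        effect_sum=eff_sum,
        effect_sq_sum=eff_sq,
        effect_draws=draws,
        pi_draws=pi_draws,
        sigma2_b_draws=s2b_draws,
        sigma2_e_draws=s2e_draws,
        n_iter=n_iter,
        burnin=burnin,
        thin=thin,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# single-marker association scan


def _residualize(W: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Project the columns of M off the column space of W."""
    Q, _ = np.linalg.qr(W)
    return M - Q @ (Q.T @ M)


def _scan_core(y, X, W):
    """Per-marker OLS slope/SE/P with covariates W, fully vectorized."""
    n = len(y)
    y_t = _residualize(W, y[:, None])[:, 0]
    X_t = _residualize(W, X)
    sxx = np.sum(X_t**2, axis=0)
    poly = sxx > 1e-12 * n
    beta = np.zeros(X.shape[1])
    se = np.full(X.shape[1], np.inf)
    pval = np.ones(X.shape[1])
    df = n - W.shape[1] - 1
    sxy = X_t.T @ y_t
    beta[poly] = sxy[poly] / sxx[poly]
    ssr = np.sum(y_t**2) - beta**2 * sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.maximum(ssr, 0.0) / df
        se[poly] = np.sqrt(s2[poly] / sxx[poly])
        tstat = np.where(se > 0, beta / se, 0.0)
    pval[poly] = 2.0 * stats.t.sf(np.abs(tstat[poly]), df)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    return beta, se, pval


def _reml_ratio(y, W, K):
    """Null-model REML for y = Wb + g + e with g ~ N(0, sg*K): one eigendecomposition.

    Returns eigenvectors, eigenvalues and the ratio sg/se maximizing the
    restricted likelihood (0 means no genetic component).
    """
    vals, vecs = np.linalg.eigh(K)
    vals = np.maximum(vals, 0.0)
    yr = vecs.T @ y
    Wr = vecs.T @ W

    def neg_restricted_ll(log_ratio):
        lam = np.exp(log_ratio)
        w = lam * vals + 1.0
        Ww = Wr / w[:, None]
        A = Wr.T @ Ww
        bhat = np.linalg.solve(A, Ww.T @ yr)
        res = yr - Wr @ bhat
        df = len(y) - W.shape[1]
        rss = np.sum(res**2 / w)
        ll = -0.5 * (
            df * np.log(rss) + np.sum(np.log(w)) + np.linalg.slogdet(A)[1]
        )
        return -ll

    opt = optimize.minimize_scalar(neg_restricted_ll, bounds=(-10, 10), method="bounded")
    ratio = float(np.exp(opt.x))
    if neg_restricted_ll(-25) <= opt.fun:  # boundary: no genetic variance
        ratio = 0.0
    return vecs, vals, ratio


def gwas_scan(
    y: np.ndarray,
    G: GenotypeMatrix | np.ndarray,
    covariates: np.ndarray | None = None,
    mode: str = "ols",
) -> pd.DataFrame:
    """Per-marker association scan (effect, SE, Wald P).

    ``ols`` regresses y on intercept + covariates + one marker at a time.
    ``mlm`` adds a polygenic random effect with a VanRaden GRM; variance
    components are estimated once on the null model and each marker is then
    tested by generalized least squares.  Monomorphic markers get estimate 0
    and P = 1 by convention.  Missing dosages are marker-mean imputed for
    the scan; rows with missing y are dropped.
    """
    if isinstance(G, GenotypeMatrix):
        X = G.dosages.copy()
        marker_ids = G.marker_ids
        chrom = G.chromosome
        pos = G.position_bp
    else:
        X = np.asarray(G, dtype=float).copy()
        marker_ids = np.array([f"m{i}" for i in range(X.shape[1])], dtype=object)
        chrom = pos = None
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    X = X[keep]
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)[keep]
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = col_mean[idx[1]]
    n = len(y)
    obs_per_marker = n
    if obs_per_marker < 3:
        raise ValueError("need at least 3 non-missing samples")
    W = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])

    if mode == "ols":
        beta, se, pval = _scan_core(y, X, W)
    elif mode == "mlm":
        from .prediction_cv import vanraden_grm

        K = vanraden_grm(X).matrix
        vecs, vals, ratio = _reml_ratio(y, W, K)
        if ratio == 0.0:
            beta, se, pval = _scan_core(y, X, W)
        else:
            w = np.sqrt(ratio * vals + 1.0)
            yr = (vecs.T @ y) / w
            Xr = (vecs.T @ X) / w[:, None]
            Wr = (vecs.T @ W) / w[:, None]
            beta, se, pval = _scan_core(yr, Xr, Wr)
    else:
        raise ValueError(f"unknown scan mode {mode!r}")

    out = pd.DataFrame(
        {
            "marker_id": marker_ids,
            "beta": beta,
            "se": se,
            "p": pval,
        }
    )
    if chrom is not None:
        out.insert(1, "chromosome", chrom)
    if pos is not None:
        out.insert(2, "position_bp", pos)
    return out
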