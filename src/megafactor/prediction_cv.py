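"""Genomic prediction: kernels, GBLUP baselines, masked cross-validation.

Implements the VanRaden genomic relationship matrix, a secondary-trait
(e.g. hyperspectral reflectance) relationship matrix H = S S'/c with S the
centered-and-standardized trait BLUEs and c the number of columns, one- and
two-kernel GBLUP with REML variance components, repeated masked
cross-validation, heritability-corrected prediction accuracy and the
repeat-correlation-adjusted t statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .io_formats import GenotypeMatrix

__all__ = [
    "KernelMatrix",
    "CvPlan",
    "vanraden_grm",
    "reflectance_kernel",
    "gblup_fit",
    "make_cv_plan",
    "corrected_accuracy",
    "adjusted_t",
]


@dataclass
class KernelMatrix:
    """Symmetric PSD relationship matrix with sample ids."""

    matrix: np.ndarray
    sample_ids: np.ndarray | None = None
    kind: str = "genomic"

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("kernel must be symmetric")
        self.matrix = 0.5 * (M + M.T)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def vanraden_grm(G: GenotypeMatrix | np.ndarray) -> KernelMatrix:
    """VanRaden GRM: K = Z Z' / (2 sum f_l (1 - f_l)), Z centered by 2 f_l.

    Missing dosages are marker-mean imputed first; monomorphic markers are
    excluded with a warning (they contribute nothing to relatedness).
    """
    if isinstance(G, GenotypeMatrix):
        X = G.dosages.copy()
        ids = G.sample_ids
    else:
        X = np.asarray(G, dtype=float).copy()
        ids = None
    if np.isnan(X).any():
        mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = mean[idx[1]]
    f = X.mean(axis=0) / 2.0
    poly = (f > 0) & (f < 1)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic markers from the GRM")
    X, f = X[:, poly], f[poly]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic markers for the GRM")
    Z = X - 2.0 * f
    denom = 2.0 * np.sum(f * (1.0 - f))
    return KernelMatrix(matrix=(Z @ Z.T) / denom, sample_ids=ids, kind="genomic")


def reflectance_kernel(S: np.ndarray, sample_ids: np.ndarray | None = None) -> KernelMatrix:
    """Secondary-trait kernel H = S S' / c from centered, standardized columns.

    Standardization is performed internally; zero-variance columns are
    dropped.  The divisor c is the number of retained columns, so
    trace(H)/n is approximately 1.
    """
    S = np.asarray(S, dtype=float)
    Sc = S - S.mean(axis=0)
    sd = Sc.std(axis=0, ddof=1)
    ok = sd > 0
    if not ok.any():
        raise ValueError("all columns are constant")
    Z = Sc[:, ok] / sd[ok]
    c = int(ok.sum())
    return KernelMatrix(matrix=(Z @ Z.T) / c, sample_ids=sample_ids, kind="reflectance")


# ---------------------------------------------------------------------------
# GBLUP


def _reml_1k(vals, yr, onesr):
    """Profile REML over the ratio sg/se for one (eigendecomposed) kernel.

    ``yr`` and ``onesr`` are the phenotype and intercept column rotated into
    the kernel's eigenbasis.
    """
    n = len(yr)

    def nll(log_ratio):
        lam = np.exp(log_ratio)
        w = lam * vals + 1.0
        denom = np.sum(onesr**2 / w)
        mu = np.sum(onesr * yr / w) / denom
        rss = np.sum((yr - mu * onesr) ** 2 / w)
        return 0.5 * ((n - 1) * np.log(rss) + np.sum(np.log(w)) + np.log(denom))

    opt = optimize.minimize_scalar(nll, bounds=(-12, 12), method="bounded")
    ratio = float(np.exp(opt.x))
    if nll(-30) <= opt.fun:
        ratio = 0.0
    return ratio


def gblup_fit(
    y: np.ndarray,
    kernels: KernelMatrix | list[KernelMatrix],
    train_idx: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """GBLUP with one or two kernels; REML variance components.

    Fits y = mu + sum_m g_m + e on the training rows (g_m ~ N(0, v_m K_m))
    and returns BLUP predictions of the total random value for every sample
    (masked ones included) plus the variance components.  One kernel uses a
    profiled eigendecomposition REML; two kernels optimize the restricted
    likelihood over both variance ratios by bounded quasi-Newton with
    restarts.
    """
    if isinstance(kernels, KernelMatrix):
        kernels = [kernels]
    if not 1 <= len(kernels) <= 2:
        raise ValueError("one or two kernels supported")
    y = np.asarray(y, dtype=float)
    n = len(y)
    if train_idx is None:
        train_idx = np.where(~np.isnan(y))[0]
    train_idx = np.asarray(train_idx)
    yt = y[train_idx]
    if np.isnan(yt).any():
        raise ValueError("training phenotypes contain missing values")
    Ks = [k.matrix for k in kernels]
    Kt = [K[np.ix_(train_idx, train_idx)] for K in Ks]
    m = len(yt)

    if len(Ks) == 1:
        vals, vecs = np.linalg.eigh(Kt[0])
        vals = np.maximum(vals, 0.0)
        yr = vecs.T @ yt
        onesr = vecs.T @ np.ones(m)
        ratio = _reml_1k(vals, yr, onesr)
        w = ratio * vals + 1.0
        mu = float(np.sum(onesr * yr / w) / np.sum(onesr**2 / w))
        res_r = yr - mu * onesr
        sigma2_e = float(np.sum(res_r**2 / w) / (m - 1))
        sigma2_g = ratio * sigma2_e
        Vinv_res = vecs @ (res_r / w) / sigma2_e
        u = sigma2_g * Ks[0][:, train_idx] @ Vinv_res
        vc = {"sigma2_g": sigma2_g, "sigma2_e": sigma2_e}
        return mu + u, vc

    # two kernels: optimize restricted log-likelihood over log variance ratios
    ones = np.ones((m, 1))

    def nll(log_ratios):
        r1, r2 = np.exp(log_ratios)
        V = r1 * Kt[0] + r2 * Kt[1] + np.eye(m)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e10
        sol = np.linalg.solve(L, np.column_stack([yt, ones[:, 0]]))
        yv, ov = sol[:, 0], sol[:, 1]
        denom = ov @ ov
        mu = (ov @ yv) / denom
        rss = np.sum((yv - mu * ov) ** 2)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        return 0.5 * ((m - 1) * np.log(rss) + logdet + np.log(denom))

    best = None
    for start in ([0.0, 0.0], [1.0, -1.0], [-1.0, 1.0]):
        res = optimize.minimize(
            nll, np.array(start), method="L-BFGS-B", bounds=[(-10, 10)] * 2
        )
        if best is None or res.fun < best.fun:
            best = res
    r1, r2 = np.exp(best.x)
    V = r1 * Kt[0] + r2 * Kt[1] + np.eye(m)
    Vinv = np.linalg.inv(V)
    denom = float(ones[:, 0] @ Vinv @ ones[:, 0])
    mu = float(ones[:, 0] @ Vinv @ yt) / denom
    res_t = yt - mu
    sigma2_e = float(res_t @ Vinv @ res_t) / (m - 1)
    alpha = Vinv @ res_t
    u = (r1 * Ks[0][:, train_idx] + r2 * Ks[1][:, train_idx]) @ alpha
    vc = {
        "sigma2_g1": r1 * sigma2_e,
        "sigma2_g2": r2 * sigma2_e,
        "sigma2_e": sigma2_e,
    }
    return mu + u, vc


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CvPlan:
    """Reproducible repeated masking plan."""

    masks: list[np.ndarray]
    fraction: float
    seed: int

    @property
    def reps(self) -> int:
        return len(self.masks)


def make_cv_plan(n: int, fraction: float = 0.5, reps: int = 20, seed: int = 0) -> CvPlan:
    """Draw ``reps`` independent masked-sample index sets of size round(fraction*n)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    size = int(round(fraction * n))
    masks = [np.sort(rng.choice(n, size=size, replace=False)) for _ in range(reps)]
    return CvPlan(masks=masks, fraction=fraction, seed=seed)


def corrected_accuracy(u_hat_test: np.ndarray, y_test: np.ndarray, h2_focal: float) -> float:
    """Prediction accuracy corrected by focal-trait heritability.

    cor(u_hat, y_test) / sqrt(h2): dividing the phenotypic correlation by
    the accuracy ceiling sqrt(h2) estimates the genetic correlation, which
    is the honest metric when secondary traits of test individuals stay
    observed during fitting.
    """
    if not 0.0 < h2_focal <= 1.0:
        raise ValueError("h2_focal must lie in (0, 1]")
    u = np.asarray(u_hat_test, dtype=float)
    y = np.asarray(y_test, dtype=float)
    ok = ~(np.isnan(u) | np.isnan(y))
    u, y = u[ok], y[ok]
    if u.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input; accuracy undefined")
    return float(np.corrcoef(u, y)[0, 1] / np.sqrt(h2_focal))


def adjusted_t(d: np.ndarray, n1: int, n2: int) -> float:
    """Repeat-correlation-adjusted t statistic for paired CV differences.

    t = mean(d) / sqrt((1/reps + n2/n1) * var(d)), with n1/n2 the training
    and testing set sizes.  Because validation data are re-used across
    repeats, the naive one-sample t is anti-conservative; the extra n2/n1
    term inflates the denominator accordingly.  Zero variance with nonzero
    mean returns signed infinity.
    """
    d = np.asarray(d, dtype=float)
    reps = len(d)
    if reps < 2:
        raise ValueError("need at least 2 repetitions")
    mean = d.mean()
    s2 = d.var(ddof=1)
    denom2 = (1.0 / reps + n2 / n1) * s2
    if denom2 == 0:
        return 0.0 if mean == 0 else float(np.sign(mean) * np.inf)
    return float(mean / np.sqrt(denom2))
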