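"""MCMC convergence and model-adequacy checks.

Includes rank-normalized split R-hat over multiple chains of a scalar
functional (by convention the genetic variance of the focal trait), the
factor-tail check verifying that the shrinkage ladder has driven the last
rows of Lambda to near zero (i.e. K was chosen large enough), and the
extraction of trace tables for the largest loadings of each factor.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["split_rhat", "factor_tail_check", "top_loading_traces"]


def _split_chains(chains: np.ndarray) -> np.ndarray:
    """Split each chain in half, doubling the chain count."""
    m, n = chains.shape
    half = n // 2
    return np.vstack([chains[:, :half], chains[:, n - half :]])


def _rank_normalize(chains: np.ndarray) -> np.ndarray:
    """Pooled fractional ranks mapped through the normal quantile function."""
    flat = chains.ravel()
    ranks = stats.rankdata(flat, method="average").reshape(chains.shape)
    size = flat.size
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (size + 1.0 / 4.0))


def _rhat_basic(chains: np.ndarray) -> float:
    """Classic potential scale reduction on already-split chains."""
    m, n = chains.shape
    chain_means = chains.mean(axis=1)
    chain_vars = chains.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def split_rhat(chains: np.ndarray | list[np.ndarray]) -> float:
    """Rank-normalized split R-hat of a scalar functional.

    ``chains`` is (m, n) with m >= 2 chains of equal length n >= 4.  Both
    the rank-normalized draws and the rank-normalized folded draws
    (|x - median|) are assessed and the larger R-hat returned.  Constant
    chains give 1.0 by convention.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    if n < 4:
        raise ValueError("need at least 4 draws per chain")
    if np.ptp(chains) == 0:
        return 1.0
    split = _split_chains(chains)
    bulk = _rhat_basic(_rank_normalize(split))
    folded = _rhat_basic(_rank_normalize(np.abs(split - np.median(split))))
    return float(max(bulk, folded))


@dataclass
class TailCheckResult:
    passed: bool
    tol: float
    tail_max: np.ndarray  # per tail row, max |posterior-mean loading|
    recommendation: str


def factor_tail_check(
    Lambda_draws: np.ndarray, n_tail: int = 5, tol: float | None = None
) -> TailCheckResult:
    """Check that the last factor rows of Lambda carry only small loadings.

    The multiplicative shrinkage ladder should push rows beyond the active
    rank toward zero; if the posterior-mean absolute loadings in the last
    ``n_tail`` rows exceed ``tol`` (default: 5% of the largest absolute
    posterior-mean loading), the chosen K was too small and the check
    recommends re-running with a larger K.
    """
    draws = np.asarray(Lambda_draws, dtype=float)
    post_mean = np.abs(draws.mean(axis=0))  # (K, t)
    K = post_mean.shape[0]
    if tol is None:
        tol = 0.05 * float(post_mean.max()) if post_mean.max() > 0 else 0.05
    if K <= n_tail:
        warnings.warn(f"K={K} <= n_tail={n_tail}; comparing all rows")
        n_tail = K
    tail = post_mean[K - n_tail :]
    tail_max = tail.max(axis=1)
    passed = bool(np.all(tail_max < tol))
    rec = (
        "tail rows are small; K is large enough"
        if passed
        else "tail rows carry substantial loadings; re-run with a larger K"
    )
    return TailCheckResult(passed=passed, tol=float(tol), tail_max=tail_max, recommendation=rec)


def top_loading_traces(Lambda_draws: np.ndarray, per_factor: int = 5) -> pd.DataFrame:
    """Plot-ready trace table of the largest loadings of each factor.

    For every factor the ``per_factor`` traits with the largest absolute
    posterior-mean loading are selected (capped at t) and their draw
    sequences emitted in long format (draw, factor, trait, value).  The
    selection is deterministic: ties break by trait index.
    """
    draws = np.asarray(Lambda_draws, dtype=float)
    n_draws, K, t = draws.shape
    post_mean = np.abs(draws.mean(axis=0))
    records = []
    take = min(per_factor, t)
    for k in range(K):
        order = np.lexsort((np.arange(t), -post_mean[k]))[:take]
        for j in order:
            records.append(
                pd.DataFrame(
                    {
                        "draw": np.arange(n_draws),
                        "factor": k,
                        "trait": j,
                        "value": draws[:, k, j],
                    }
                )
            )
    return pd.concat(records, ignore_index=True)
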