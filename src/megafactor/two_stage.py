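"""Two-stage association pipeline: scan, LD clumping, Bayesian stage 2.

Stage 1 runs a single-marker scan on the partition of individuals that have
only the focal trait, then greedily clumps the survivors (keep the most
significant marker, mask everything within a window in strong LD with it).
Stage 2 fits ST-BayesC or the sparse-factor model on the other partition
restricted to the clumped candidates; markers never selected are implicitly
zero.  Post-processing covers marker-explained variance, significance
classification and SNP-to-gene matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneTable, GenotypeMatrix, PhenotypeBlock
from .model_core import (
    Hyperparameters,
    ModelData,
    fixed_first_factor_spec,
    focal_marker_effects,
    run_mcmc,
)
from .single_trait import gwas_scan, st_bayesc_fit

__all__ = [
    "CandidateSet",
    "pairwise_r2",
    "ld_prune",
    "clump_select",
    "run_two_stage",
    "marker_explained_variance",
    "classify_significant",
    "match_snps_to_genes",
]


@dataclass
class CandidateSet:
    """Ordered stage-1 candidates (most significant first)."""

    marker_ids: np.ndarray
    marker_index: np.ndarray  # positions in the source genotype matrix
    p_values: np.ndarray
    p_max: float
    window_bp: int
    r2_max: float

    def __len__(self) -> int:
        return len(self.marker_ids)


def pairwise_r2(G: GenotypeMatrix | np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage columns over shared samples.

    Monomorphic columns give 0 by convention.
    """
    X = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    a, b = X[:, i], X[:, j]
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _corr_sq(X: np.ndarray) -> np.ndarray:
    """Pairwise r^2 of columns; monomorphic columns give 0 rows/cols."""
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(Xc)
    Z[:, ok] = Xc[:, ok] / sd[ok]
    C = (Z.T @ Z) / X.shape[0]
    return C * C


def _maf_of(X: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        f = np.nanmean(X, axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def ld_prune(
    G: GenotypeMatrix,
    r2_max: float = 0.8,
    window: int = 500,
    step: int = 100,
) -> np.ndarray:
    """Sliding-window LD pruning; returns retained marker indices in order.

    Within each window of ``window`` markers (slid by ``step``), any pair
    with r^2 > r2_max loses its lower-MAF member (ties drop the later
    marker).  Markers must be position-sorted within chromosome.
    """
    X = np.where(np.isnan(G.dosages), np.nanmean(G.dosages, axis=0), G.dosages)
    maf = _maf_of(X)
    chroms = G.chromosome if G.chromosome is not None else np.repeat("1", G.n_markers)
    keep = np.ones(G.n_markers, dtype=bool)
    for chrom in pd.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        m = len(idx)
        start = 0
        while True:
            win = idx[start : start + window]
            cand = win[keep[win]]
            if len(cand) > 1:
                C2 = _corr_sq(X[:, cand])
                np.fill_diagonal(C2, 0.0)
                local_keep = np.ones(len(cand), dtype=bool)
                while True:
                    sub = np.where(local_keep)[0]
                    Cs = C2[np.ix_(sub, sub)]
                    hit = np.argwhere(Cs > r2_max)
                    hit = hit[hit[:, 0] < hit[:, 1]]
                    if len(hit) == 0:
                        break
                    a, b = sub[hit[0, 0]], sub[hit[0, 1]]
                    ga, gb = cand[a], cand[b]
                    drop = a if maf[ga] < maf[gb] else b  # tie -> later marker
                    local_keep[drop] = False
                keep[cand[~local_keep]] = False
            if start + window >= m:
                break
            start += step
    return np.where(keep)[0]


def clump_select(
    gwas: pd.DataFrame,
    G: GenotypeMatrix,
    p_max: float = 0.01,
    window_bp: int = 250_000,
    r2_max: float = 0.5,
) -> CandidateSet:
    """Greedy LD clumping of a scan result.

    Drop markers with P > p_max; then repeatedly take the most significant
    unmasked survivor and permanently mask every marker within +/- window_bp
    on its chromosome with r^2 > r2_max.  Ties on P break by genomic
    position, then marker id, so the output is invariant to input order.
    """
    if G.position_bp is None:
        raise ValueError("clumping requires marker positions")
    df = gwas.set_index("marker_id")
    order = {mid: k for k, mid in enumerate(G.marker_ids)}
    df = df.loc[[m for m in df.index if m in order]]
    df = df[df["p"] <= p_max]
    if df.empty:
        return CandidateSet(
            marker_ids=np.array([], dtype=object),
            marker_index=np.array([], dtype=int),
            p_values=np.array([]),
            p_max=p_max,
            window_bp=window_bp,
            r2_max=r2_max,
        )
    idx = np.array([order[m] for m in df.index])
    pos = G.position_bp[idx]
    chrom = (
        G.chromosome[idx] if G.chromosome is not None else np.repeat("1", len(idx))
    )
    pvals = df["p"].to_numpy()
    rank = np.lexsort((np.asarray(df.index, dtype=object), pos, pvals))

    X = np.where(np.isnan(G.dosages), np.nanmean(G.dosages, axis=0), G.dosages)
    masked = np.zeros(len(idx), dtype=bool)
    taken: list[int] = []
    for r in rank:
        if masked[r]:
            continue
        taken.append(r)
        near = (
            (chrom == chrom[r])
            & (np.abs(pos - pos[r]) <= window_bp)
            & ~masked
        )
        near[r] = False
        near_idx = np.where(near)[0]
        if len(near_idx):
            x0 = X[:, idx[r]]
            sd0 = x0.std()
            if sd0 == 0:
                continue
            z0 = (x0 - x0.mean()) / sd0
            Xn = X[:, idx[near_idx]]
            Xc = Xn - Xn.mean(axis=0)
            sd = Xc.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = (z0 @ Xc / len(z0)) ** 2 / np.where(sd > 0, sd**2, np.inf)
            masked[near_idx[r2 > r2_max]] = True
        masked[r] = True
    taken = np.array(taken, dtype=int)
    return CandidateSet(
        marker_ids=np.array(df.index, dtype=object)[taken],
        marker_index=idx[taken],
        p_values=pvals[taken],
        p_max=p_max,
        window_bp=window_bp,
        r2_max=r2_max,
    )


def run_two_stage(
    G: GenotypeMatrix,
    pheno: PhenotypeBlock,
    idx_stage1: np.ndarray,
    idx_stage2: np.ndarray,
    method: str = "megabayesc",
    p_max: float = 0.01,
    window_bp: int = 250_000,
    r2_max: float = 0.5,
    n_iter: int = 4_000,
    burnin: int = 1_000,
    thin: int = 2,
    seed: int = 0,
    n_factors: int = 10,
    scan_mode: str = "ols",
) -> tuple[pd.DataFrame, CandidateSet]:
    """Full two-stage analysis.

    Stage 1: single-marker scan of the focal trait on the ``idx_stage1``
    partition (individuals without secondary traits), then LD clumping.
    Stage 2: the chosen Bayesian method on the ``idx_stage2`` partition
    restricted to the clumped candidates.  The factor-model stage 2 uses the
    fixed-first-factor construction so candidates can act directly on the
    focal trait.  Returns a per-marker effect table over all markers
    (non-candidates have effect 0) plus the candidate set.
    """
    idx_stage1 = np.asarray(idx_stage1)
    idx_stage2 = np.asarray(idx_stage2)
    if np.intersect1d(idx_stage1, idx_stage2).size:
        raise ValueError("stage-1 and stage-2 partitions overlap")

    y_a = pheno.values[idx_stage1, pheno.focal_index]
    G_a = G.subset_samples(idx_stage1)
    scan = gwas_scan(y_a, G_a, mode=scan_mode)
    cands = clump_select(scan, G, p_max=p_max, window_bp=window_bp, r2_max=r2_max)

    p = G.n_markers
    effects = np.zeros(p)
    if len(cands) == 0:
        warnings.warn("stage 1 selected no candidates; all effects set to 0")
    else:
        Xb = G.dosages[np.ix_(idx_stage2, cands.marker_index)]
        Xb = np.where(np.isnan(Xb), np.nanmean(Xb, axis=0), Xb)
        if method == "st_bayesc":
            y_b = pheno.values[idx_stage2, pheno.focal_index]
            fit = st_bayesc_fit(
                y_b, Xb, n_iter=n_iter, burnin=burnin, thin=thin, seed=seed
            )
            effects[cands.marker_index] = fit.effects
        elif method == "megabayesc":
            Yb = pheno.values[idx_stage2]
            K = min(n_factors, len(idx_stage2), pheno.n_traits)
            hyper = Hyperparameters(
                n_factors=K,
                fixed_loadings=fixed_first_factor_spec(K, pheno.n_traits, pheno.focal_index),
            )
            data = ModelData(Y=Yb, X2F=Xb, focal_index=pheno.focal_index)
            chain = run_mcmc(
                data, hyper, n_iter=n_iter, burnin=burnin, thin=thin, seed=seed
            )
            effects[cands.marker_index] = focal_marker_effects(chain)
        else:
            raise ValueError(f"unknown stage-2 method {method!r}")

    y_focal = pheno.focal
    total_var = float(np.nanvar(y_focal))
    Ximp = np.where(np.isnan(G.dosages), np.nanmean(G.dosages, axis=0), G.dosages)
    ev = effects**2 * np.var(Ximp, axis=0)
    table = pd.DataFrame(
        {
            "marker_id": G.marker_ids,
            "chromosome": G.chromosome if G.chromosome is not None else "1",
            "position_bp": G.position_bp if G.position_bp is not None else 0,
            "estimate": effects,
            "explained_variance": ev,
            "explained_proportion": ev / total_var if total_var > 0 else np.nan,
            "candidate": np.isin(np.arange(p), cands.marker_index),
        }
    )
    return table, cands


def marker_explained_variance(
    alpha_l: float, x_l: np.ndarray, y_focal: np.ndarray | None = None
) -> tuple[float, float | None]:
    """Empirical variance of a marker's contribution alpha_l * x_l.

    Returns (variance, proportion of focal-trait variance) — the proportion
    is None unless the focal phenotype vector is supplied.
    """
    x_l = np.asarray(x_l, dtype=float)
    var = float(np.var(alpha_l * x_l[~np.isnan(x_l)]))
    prop = None
    if y_focal is not None:
        total = float(np.nanvar(np.asarray(y_focal, dtype=float)))
        prop = var / total if total > 0 else np.nan
    return var, prop


def classify_significant(results: pd.DataFrame, rule: str = "explained_variance") -> pd.DataFrame:
    """Flag significant markers.

    ``explained_variance``: explained proportion strictly > 0.1%.
    ``pvalue``: P strictly < 1e-5.
    """
    out = results.copy()
    if rule == "explained_variance":
        out["significant"] = out["explained_proportion"] > 0.001
    elif rule == "pvalue":
        out["significant"] = out["p"] < 1e-5
    else:
        raise ValueError(f"unknown significance rule {rule!r}")
    return out


def match_snps_to_genes(
    snps: pd.DataFrame,
    genes: GeneTable,
    window_bp: int = 100_000,
) -> tuple[pd.DataFrame, dict]:
    """Match SNPs to gene intervals within +/- window_bp (inclusive).

    A SNP matches a gene when its position lies in
    [start - window_bp, end + window_bp] on the same chromosome.  Returns a
    per-SNP table with the matched gene list and a true/false-positive tally
    over the SNPs flagged significant (all SNPs if no ``significant``
    column is present).
    """
    matched_genes = []
    is_match = np.zeros(len(snps), dtype=bool)
    for k, row in enumerate(snps.itertuples(index=False)):
        chrom = str(row.chromosome)
        pos = int(row.position_bp)
        hits = [
            str(genes.gene_ids[g])
            for g in range(len(genes.gene_ids))
            if str(genes.chromosome[g]) == chrom
            and genes.start_bp[g] - window_bp <= pos <= genes.end_bp[g] + window_bp
        ]
        matched_genes.append(",".join(hits))
        is_match[k] = bool(hits)
    out = snps.copy()
    out["matched_genes"] = matched_genes
    out["gene_match"] = is_match
    sig = out["significant"].to_numpy() if "significant" in out else np.ones(len(out), bool)
    tally = {
        "n_significant": int(sig.sum()),
        "true_positives": int((sig & is_match).sum()),
        "false_positives": int((sig & ~is_match).sum()),
    }
    return out, tally
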