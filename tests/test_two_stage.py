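"""LD pruning, greedy clumping, the two-stage pipeline and post-processing."""

import numpy as np
import pandas as pd
import pytest

from megafactor.io_formats import GeneTable, GenotypeMatrix, PhenotypeBlock
from megafactor.single_trait import gwas_scan, st_bayesc_fit
from megafactor.two_stage import (
    clump_select,
    classify_significant,
    ld_prune,
    marker_explained_variance,
    match_snps_to_genes,
    pairwise_r2,
    run_two_stage,
)


def _geno(dosages, pos=None, chrom=None):
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        marker_ids=np.array([f"m{j}" for j in range(p)], dtype=object),
        chromosome=np.repeat("1", p) if chrom is None else chrom,
        position_bp=np.arange(1, p + 1) * 1000 if pos is None else np.asarray(pos),
    )


class TestPairwiseR2:
    def test_identical_columns(self, rng):
        x = rng.integers(0, 3, 20).astype(float)
        G = _geno(np.column_stack([x, x]))
        assert pairwise_r2(G, 0, 1) == pytest.approx(1.0)

    def test_orthogonal_columns(self):
        a = np.array([0.0, 2.0, 0.0, 2.0])
        b = np.array([0.0, 0.0, 2.0, 2.0])
        G = _geno(np.column_stack([a, b]))
        assert pairwise_r2(G, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_correlation(self, rng):
        a = rng.integers(0, 3, 10).astype(float)
        b = np.clip(a + rng.integers(-1, 2, 10), 0, 2).astype(float)
        G = _geno(np.column_stack([a, b]))
        expected = np.corrcoef(a, b)[0, 1] ** 2
        assert pairwise_r2(G, 0, 1) == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_is_zero(self, rng):
        a = np.full(10, 2.0)
        b = rng.integers(0, 3, 10).astype(float)
        assert pairwise_r2(_geno(np.column_stack([a, b])), 0, 1) == 0.0


class TestLdPrune:
    def test_duplicate_marker_one_survives(self, rng):
        x = rng.integers(0, 3, 30).astype(float)
        others = rng.integers(0, 3, (30, 3)).astype(float)
        G = _geno(np.column_stack([x, others[:, 0], x, others[:, 1:]]))
        kept = ld_prune(G, r2_max=0.8, window=5, step=2)
        assert (0 in kept) != (2 in kept)

    def test_independent_markers_all_kept(self, rng):
        G = _geno(rng.integers(0, 3, (500, 20)).astype(float))
        kept = ld_prune(G, r2_max=0.8, window=10, step=5)
        assert len(kept) == 20

    def test_postcondition_brute_force(self, rng):
        """60 correlated markers: no retained intra-window pair exceeds the
        threshold, verified by an all-pairs check."""
        n, p = 200, 60
        base = rng.integers(0, 3, (n, p)).astype(float)
        # induce strong local correlation by copying neighbours
        for j in range(1, p):
            copy = rng.random(n) < 0.8
            base[copy, j] = base[copy, j - 1]
        G = _geno(base)
        window, r2_max = 20, 0.8
        kept = ld_prune(G, r2_max=r2_max, window=window, step=10)
        kept = list(kept)
        for a_i in range(len(kept)):
            for b_i in range(a_i + 1, len(kept)):
                ka, kb = kept[a_i], kept[b_i]
                if kb - ka < window:  # same window at some slide position
                    assert pairwise_r2(G, ka, kb) <= r2_max + 1e-12


def _brute_force_clump(gwas, G, p_max, window_bp, r2_max):
    """Independent greedy reference used as the clumping oracle."""
    df = gwas[gwas["p"] <= p_max].copy()
    idx = {m: i for i, m in enumerate(G.marker_ids)}
    df["gi"] = [idx[m] for m in df["marker_id"]]
    df["pos"] = G.position_bp[df["gi"].to_numpy()]
    alive = df.sort_values(["p", "pos", "marker_id"]).reset_index(drop=True)
    taken = []
    while len(alive):
        top = alive.iloc[0]
        taken.append(top["marker_id"])
        keep_rows = []
        for _, row in alive.iloc[1:].iterrows():
            near = abs(row["pos"] - top["pos"]) <= window_bp
            if near and pairwise_r2(G, int(top["gi"]), int(row["gi"])) > r2_max:
                continue
            keep_rows.append(row)
        alive = pd.DataFrame(keep_rows).reset_index(drop=True)
    return taken


class TestClumpSelect:
    def test_all_p_large_empty(self, rng):
        G = _geno(rng.integers(0, 3, (20, 5)).astype(float))
        gwas = pd.DataFrame({"marker_id": G.marker_ids, "p": np.full(5, 0.5)})
        cands = clump_select(gwas, G)
        assert len(cands) == 0

    def test_greedy_keeps_most_significant_of_linked_pair(self, rng):
        x = rng.integers(0, 3, 50).astype(float)
        G = _geno(np.column_stack([x, x]), pos=[10_000, 11_000])
        gwas = pd.DataFrame({"marker_id": ["m0", "m1"], "p": [1e-8, 1e-4]})
        cands = clump_select(gwas, G)
        assert list(cands.marker_ids) == ["m0"]

    def test_matches_brute_force_oracle(self, rng):
        n, p = 150, 100
        dos = rng.integers(0, 3, (n, p)).astype(float)
        for j in range(1, p):
            copy = rng.random(n) < 0.6
            dos[copy, j] = dos[copy, j - 1]
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), p, replace=False))
        G = _geno(dos, pos=pos)
        gwas = pd.DataFrame(
            {"marker_id": G.marker_ids, "p": 10 ** (-rng.uniform(0, 6, p))}
        )
        cands = clump_select(gwas, G, p_max=0.01, window_bp=250_000, r2_max=0.5)
        oracle = _brute_force_clump(gwas, G, 0.01, 250_000, 0.5)
        assert list(cands.marker_ids) == oracle

    def test_input_order_invariance(self, rng):
        n, p = 80, 40
        dos = rng.integers(0, 3, (n, p)).astype(float)
        G = _geno(dos)
        gwas = pd.DataFrame(
            {"marker_id": G.marker_ids, "p": 10 ** (-rng.uniform(0, 5, p))}
        )
        a = clump_select(gwas, G)
        b = clump_select(gwas.sample(frac=1.0, random_state=1), G)
        assert list(a.marker_ids) == list(b.marker_ids)

    def test_postcondition_no_linked_pair(self, rng):
        n, p = 100, 50
        dos = rng.integers(0, 3, (n, p)).astype(float)
        for j in range(1, p):
            copy = rng.random(n) < 0.7
            dos[copy, j] = dos[copy, j - 1]
        G = _geno(dos)
        gwas = pd.DataFrame(
            {"marker_id": G.marker_ids, "p": 10 ** (-rng.uniform(0, 5, p))}
        )
        cands = clump_select(gwas, G, p_max=0.05, window_bp=30_000, r2_max=0.5)
        for i in range(len(cands)):
            for j in range(i + 1, len(cands)):
                a, b = cands.marker_index[i], cands.marker_index[j]
                if abs(G.position_bp[a] - G.position_bp[b]) <= 30_000:
                    assert pairwise_r2(G, int(a), int(b)) <= 0.5 + 1e-12


class TestRunTwoStage:
    def _make_data(self, rng, n=120, p=30, with_signal=True):
        dos = rng.integers(0, 3, (n, p)).astype(float)
        G = _geno(dos)
        y = rng.normal(size=n)
        if with_signal:
            y = y + 0.8 * dos[:, 5] - 0.6 * dos[:, 17]
        Y = np.column_stack([y, y * 0.5 + rng.normal(size=n)])
        pheno = PhenotypeBlock(
            values=Y,
            sample_ids=G.sample_ids,
            trait_ids=np.array(["focal", "sec"], dtype=object),
            focal_index=0,
        )
        return G, pheno

    def test_overlapping_partitions_rejected(self, rng):
        G, pheno = self._make_data(rng)
        with pytest.raises(ValueError, match="overlap"):
            run_two_stage(G, pheno, np.arange(60), np.arange(50, 120))

    def test_empty_candidates_warns_and_zeroes(self, rng):
        G, pheno = self._make_data(rng, with_signal=False)
        with pytest.warns(UserWarning, match="no candidates"):
            table, cands = run_two_stage(
                G, pheno, np.arange(60), np.arange(60, 120), p_max=1e-12,
                n_iter=200, burnin=50,
            )
        assert len(cands) == 0
        assert np.all(table["estimate"] == 0.0)

    def test_all_candidates_equals_direct_stage2(self, rng):
        """With clumping disabled (p_max=1, r2_max=1) stage 2 sees every
        marker, so the pipeline must equal a direct ST-BayesC fit on B."""
        G, pheno = self._make_data(rng)
        idx1, idx2 = np.arange(60), np.arange(60, 120)
        table, cands = run_two_stage(
            G, pheno, idx1, idx2, method="st_bayesc", p_max=1.0, r2_max=1.01,
            n_iter=600, burnin=200, seed=7,
        )
        assert len(cands) == G.n_markers
        direct = st_bayesc_fit(
            pheno.values[idx2, 0], G.dosages[np.ix_(idx2, cands.marker_index)],
            n_iter=600, burnin=200, thin=2, seed=7,
        )
        np.testing.assert_allclose(
            table["estimate"].to_numpy()[cands.marker_index],
            direct.effects,
            atol=1e-12,
        )


class TestEndToEndOrdering:
    def test_one_stage_scan_worse_than_two_stage(self, rng):
        """On LD genotypes the raw single-marker scan overestimates effects;
        the two-stage factor-model analysis achieves a lower RMSE of both
        effects and explained SDs."""
        from megafactor.simulate import (
            score_estimates,
            sim_arabidopsis_like,
            sim_ld_genotypes,
        )

        G = sim_ld_genotypes(600, 800, seed=41, rho=0.9)
        pheno, truth, part = sim_arabidopsis_like(G, seed=42)
        idx1, idx2 = part["focal_only"], part["secondary"]
        table, cands = run_two_stage(
            G, pheno, idx1, idx2, method="megabayesc",
            n_iter=1500, burnin=500, seed=43, n_factors=12,
        )
        scan = gwas_scan(pheno.focal, G, mode="ols")
        cands1 = clump_select(scan, G)
        est1 = np.zeros(G.n_markers)
        est1[cands1.marker_index] = (
            scan.set_index("marker_id").loc[cands1.marker_ids, "beta"].to_numpy()
        )
        two = score_estimates(truth, table["estimate"].to_numpy(), G, cands.marker_index)
        one = score_estimates(truth, est1, G, cands1.marker_index)
        assert two["rmse_effects"] < one["rmse_effects"]
        assert two["rmse_explained_sd"] < one["rmse_explained_sd"]


class TestPostProcessing:
    def test_explained_variance_zero_alpha(self, rng):
        var, prop = marker_explained_variance(0.0, rng.integers(0, 3, 10))
        assert var == 0.0 and prop is None

    def test_explained_variance_formula(self):
        x = np.array([0.0, 1.0, 2.0, 1.0])  # empirical variance 0.5
        var, prop = marker_explained_variance(0.1, x, y_focal=np.array([0.0, 1.0, 2.0, 3.0]))
        assert var == pytest.approx(0.01 * 0.5)
        assert prop == pytest.approx(0.01 * 0.5 / np.var([0.0, 1.0, 2.0, 3.0]))

    def test_explained_variance_additivity(self, rng):
        """Independent QTL: per-marker explained variances sum to roughly the
        total genetic variance."""
        n, q = 4000, 20
        X = rng.integers(0, 3, (n, q)).astype(float)
        alpha = rng.normal(0, 0.3, q)
        g = X @ alpha
        total = np.var(g)
        parts = sum(marker_explained_variance(alpha[j], X[:, j])[0] for j in range(q))
        assert parts == pytest.approx(total, rel=0.1)

    def test_classify_significant_boundaries(self):
        df = pd.DataFrame(
            {
                "explained_proportion": [0.001, 0.0011, 0.9, 0.0, 0.0005],
                "p": [1e-5, 9.9e-6, 0.5, 1e-20, 1.0],
            }
        )
        ev = classify_significant(df, "explained_variance")
        assert list(ev["significant"]) == [False, True, True, False, False]
        pv = classify_significant(df, "pvalue")
        assert list(pv["significant"]) == [False, True, False, True, False]

    def test_match_snps_to_genes(self):
        genes = GeneTable(
            gene_ids=np.array(["g1", "g2"], dtype=object),
            chromosome=np.array(["1", "2"], dtype=object),
            start_bp=np.array([500_000, 1_000_000]),
            end_bp=np.array([510_000, 1_020_000]),
        )
        snps = pd.DataFrame(
            {
                "marker_id": ["a", "b", "c", "d"],
                "chromosome": ["1", "1", "2", "2"],
                "position_bp": [505_000, 610_000, 1_120_000, 1_120_001],
                "significant": [True, True, True, True],
            }
        )
        out, tally = match_snps_to_genes(snps, genes, window_bp=100_000)
        # a: inside gene body; b: exactly 100 kb beyond end (inclusive);
        # c: exactly at end+100kb; d: 1 bp past the window
        assert list(out["gene_match"]) == [True, True, True, False]
        assert tally == {"n_significant": 4, "true_positives": 3, "false_positives": 1}
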