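"""Kinship, mixed-model scan, thresholds, candidate mapping and burden."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from samgwas import synthgen
from samgwas.assoc_stats import UndefinedStatisticError
from samgwas.config import SimConfig
from samgwas.gwas import (
    GeneAnnotation,
    KinshipMatrix,
    TASRecord,
    alt_burden,
    bonferroni_threshold,
    call_tas,
    compress_kinship,
    genotype_pcs,
    kinship,
    map_candidates,
    mlm_scan,
    select_model,
)
from samgwas.variants import MISSING, GenotypeMatrix


def random_matrix(n_ind, n_sites, p_alt, seed, missing=0.0):
    rng = np.random.default_rng(seed)
    p = np.broadcast_to(np.asarray(p_alt, float), (n_sites,))
    calls = np.where(rng.random((n_ind, n_sites)) < p, 2, 0).astype(np.int8)
    if missing:
        calls[rng.random((n_ind, n_sites)) < missing] = MISSING
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(n_sites) * 10,
            "com": "A",
            "alt": "T",
        }
    )
    return GenotypeMatrix([f"i{k}" for k in range(n_ind)], sites, calls, "genomic")


class TestKinship:
    def test_identical_individuals_share_diagonal(self):
        m = random_matrix(6, 200, 0.3, seed=0)
        m.calls[1] = m.calls[0]
        K = kinship(m)
        assert K.values[0, 1] == pytest.approx(K.values[0, 0], abs=1e-10)

    def test_unrelated_off_diagonal_vanishes(self):
        # independent equifrequent sites, 10,000 of them; sample-mean
        # centering leaves a small negative off-diagonal bias of order
        # diag/(n−1), so it vanishes as the panel grows
        n = 200
        m = random_matrix(n, 10_000, 0.5, seed=1)
        K = kinship(m)
        off = K.values[~np.eye(n, dtype=bool)]
        assert abs(off.mean()) < 0.02
        # inbred coding has dosage variance 4p(1−p): the VanRaden 2p(1−p)
        # denominator puts the diagonal near 2 rather than 1
        assert np.mean(np.diag(K.values)) == pytest.approx(2.0, rel=0.1)

    def test_subpopulation_block_structure(self):
        cfg = SimConfig(seed=2, n_genotypes=80, n_snps=2000, n_subpops=2, fst=0.3, missing_rate=0)
        geno = synthgen.gen_genotypes(cfg)
        sub = synthgen.subpop_assignment(cfg)
        K = kinship(geno).values
        same = K[np.equal.outer(sub, sub) & ~np.eye(80, dtype=bool)]
        diff = K[~np.equal.outer(sub, sub)]
        assert same.mean() > diff.mean()

    def test_monomorphic_matrix_rejected(self):
        m = random_matrix(5, 10, 0.0, seed=3)
        with pytest.raises(ValueError, match="monomorphic"):
            kinship(m)


class TestBonferroni:
    def test_published_scale_threshold(self):
        t = bonferroni_threshold(0.01, 923_000 + 358_000)
        assert f"{t:.2f}" == "8.11"

    @pytest.mark.parametrize("alpha,m,expect", [(0.05, 1, 1.3010), (0.01, 100, 4.0)])
    def test_small_cases(self, alpha, m, expect):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expect, abs=1e-4)

    def test_monotone_in_m(self):
        t1 = bonferroni_threshold(0.01, 1000)
        t2 = bonferroni_threshold(0.01, 2000)
        assert t2 - t1 == pytest.approx(np.log10(2), abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.01, 0)


def dense_gls_oracle(y, X, s, K, sigma2_g, sigma2_e):
    """Direct V⁻¹-weighted GLS effect and SE for one SNP (no rotation)."""
    V = sigma2_g * K + sigma2_e * np.eye(len(y))
    Vi = np.linalg.inv(V)
    D = np.column_stack([X, s])
    A = D.T @ Vi @ D
    b = np.linalg.solve(A, D.T @ Vi @ y)
    n, p1 = D.shape
    resid = y - D @ b
    sigma2 = float(resid @ Vi @ resid) / (n - p1)
    cov = sigma2 * np.linalg.inv(A)
    return b[-1], np.sqrt(cov[-1, -1])


class TestMLMScan:
    def test_identity_kinship_collapses_to_ols(self):
        rng = np.random.default_rng(7)
        m = random_matrix(80, 40, 0.3, seed=8)
        y = rng.standard_normal(80)
        K = KinshipMatrix(np.eye(80), m.individuals)
        scan = mlm_scan(y, m, K)
        import statsmodels.api as sm

        for j in [0, 5, 17]:
            x = m.calls[:, j].astype(float)
            ols = sm.OLS(y, sm.add_constant(x)).fit()
            assert 10 ** -scan.table.neglog10p[j] == pytest.approx(ols.pvalues[1], abs=1e-6)

    def test_rotation_identity_against_dense_oracle(self):
        rng = np.random.default_rng(9)
        m = random_matrix(30, 60, 0.3, seed=10)
        K = kinship(m)
        chol = np.linalg.cholesky(K.values + 1e-3 * np.eye(30))
        y = chol @ rng.standard_normal(30) + 0.5 * rng.standard_normal(30)
        scan = mlm_scan(y, m, K)
        g = m.calls.astype(float)
        X = np.ones((30, 1))
        for j in [0, 7, 33]:
            eff, se = dense_gls_oracle(y, X, g[:, j], K.values, scan.sigma2_g, scan.sigma2_e)
            assert scan.table.effect[j] == pytest.approx(eff, abs=1e-8)
            assert scan.table.se[j] == pytest.approx(se, abs=1e-8)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        m = random_matrix(40, 50, 0.2, seed=12)
        K = kinship(m)
        y = rng.standard_normal(40)
        base = mlm_scan(y, m, K).table.neglog10p.to_numpy()
        perm = rng.permutation(40)
        m2 = GenotypeMatrix(
            [m.individuals[i] for i in perm], m.sites.copy(), m.calls[perm], m.source
        )
        K2 = KinshipMatrix(K.values[np.ix_(perm, perm)], m2.individuals)
        permuted = mlm_scan(y[perm], m2, K2).table.neglog10p.to_numpy()
        np.testing.assert_allclose(base, permuted, atol=1e-6)

    def test_p3d_close_to_exact(self):
        rng = np.random.default_rng(13)
        m = random_matrix(60, 30, 0.3, seed=14)
        K = kinship(m)
        chol = np.linalg.cholesky(K.values + 1e-3 * np.eye(60))
        y = chol @ rng.standard_normal(60) + rng.standard_normal(60)
        fast = mlm_scan(y, m, K, p3d=True).table.neglog10p.to_numpy()
        exact = mlm_scan(y, m, K, p3d=False).table.neglog10p.to_numpy()
        assert np.max(np.abs(fast - exact)) < 0.2

    def test_zero_variance_phenotype_rejected(self):
        m = random_matrix(20, 10, 0.3, seed=15)
        with pytest.raises(ValueError, match="zero-variance"):
            mlm_scan(np.ones(20), m, kinship(m))


class TestSelectModel:
    def test_no_structure_prefers_zero_pcs(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = random_matrix(60, 300, 0.3, seed=1000 + seed)
            K = kinship(m)
            pcs = genotype_pcs(m, 3)
            y = rng.standard_normal(60)
            q, _ = select_model(y, K, pcs, max_pcs=3)
            wins += q == 0
        assert wins >= 80

    def test_structure_aligned_phenotype_needs_pcs(self):
        cfg = SimConfig(seed=16, n_genotypes=80, n_snps=800, n_subpops=2, fst=0.4, missing_rate=0)
        m = synthgen.gen_genotypes(cfg)
        K = kinship(m)
        pcs = genotype_pcs(m, 3)
        rng = np.random.default_rng(17)
        y = 3.0 * pcs[:, 0] + rng.standard_normal(80)
        q, _ = select_model(y, K, pcs, max_pcs=3)
        assert q >= 1

    def test_max_pcs_zero_returns_kinship_only(self):
        m = random_matrix(30, 100, 0.3, seed=18)
        y = np.random.default_rng(19).standard_normal(30)
        q, bics = select_model(y, kinship(m), genotype_pcs(m, 3), max_pcs=0)
        assert q == 0 and list(bics) == [0]


class TestCandidates:
    def test_window_assignment_distance(self):
        tas = [TASRecord("1", 500_000, "A", "T", 9.0)]
        genes = [GeneAnnotation("g1", "1", 550_000, 560_000)]
        out = map_candidates(tas, genes, window=100_000)
        assert out[0].genes == [("g1", 50_000, False)]

    def test_inside_gene_distance_zero(self):
        tas = [TASRecord("1", 555_000, "A", "T", 9.0)]
        genes = [GeneAnnotation("g1", "1", 550_000, 560_000)]
        out = map_candidates(tas, genes, window=100_000)
        assert out[0].genes == [("g1", 0, True)]

    def test_brute_force_all_pairs(self):
        rng = np.random.default_rng(20)
        tas = [TASRecord("1", int(p), "A", "T", 9.0) for p in rng.integers(0, 2_000_000, 50)]
        genes = [
            GeneAnnotation(f"g{k}", "1", int(s), int(s) + 5000)
            for k, s in enumerate(rng.integers(0, 2_000_000, 20))
        ]
        out = map_candidates(tas, genes, window=100_000)
        for rec in out:
            expected = set()
            for g in genes:
                if g.start - 100_000 <= rec.pos < g.end + 100_000:
                    expected.add(g.gene_id)
            assert {gid for gid, _, _ in rec.genes} == expected

    def test_chromosome_mismatch_yields_no_assignment(self):
        tas = [TASRecord("chrX", 100, "A", "T", 9.0)]
        out = map_candidates(tas, [GeneAnnotation("g1", "chr1", 50, 500)])
        assert out[0].genes == []


class TestAltBurden:
    def test_all_com_burden_undefined(self):
        m = random_matrix(20, 5, 0.0, seed=21)
        tas = [TASRecord("chr1", int(p), "A", "T", 9.0) for p in m.sites["pos"][:3]]
        y = np.random.default_rng(22).standard_normal(20)
        with pytest.raises(UndefinedStatisticError):
            alt_burden(tas, m, y)

    def test_noiseless_burden_perfect_correlation(self):
        m = random_matrix(30, 6, 0.3, seed=23)
        tas = [TASRecord("chr1", int(p), "A", "T", 9.0) for p in m.sites["pos"]]
        counts_true = (m.calls == 2).sum(axis=1).astype(float)
        counts, corr = alt_burden(tas, m, 2.5 * counts_true + 1.0)
        np.testing.assert_array_equal(counts, counts_true)
        assert corr.r == pytest.approx(1.0, abs=1e-12)

    def test_moderate_correlation_regime(self):
        """Five TAS with equal effects and noise tuned for r ≈ 0.5."""
        rs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = random_matrix(300, 5, 0.2, seed=3000 + seed)
            tas = [TASRecord("chr1", int(p), "A", "T", 9.0) for p in m.sites["pos"]]
            counts = (m.calls == 2).sum(axis=1).astype(float)
            noise_sd = np.sqrt(3.0) * counts.std()  # r = 1/sqrt(1+3) = 0.5
            y = counts + rng.normal(0, noise_sd, 300)
            _, corr = alt_burden(tas, m, y)
            rs.append(corr.r)
        assert abs(np.median(rs) - 0.5) < 0.1


def test_call_tas_threshold_and_indicator():
    rng = np.random.default_rng(24)
    m = random_matrix(100, 200, 0.2, seed=25)
    K = kinship(m)
    dose = m.calls[:, 10].astype(float)
    y = 2.0 * dose + rng.standard_normal(100)
    scan = mlm_scan(y, m, K, alpha=0.01)
    tas = call_tas(scan, m)
    assert any(t.pos == m.sites.loc[10, "pos"] for t in tas)
    rec = next(t for t in tas if t.pos == m.sites.loc[10, "pos"])
    np.testing.assert_array_equal(rec.alt_indicator, m.calls[:, 10] == 2)
    assert all(t.neglog10p > scan.threshold for t in tas)


def test_compress_identity_when_groups_equal_n():
    m = random_matrix(20, 100, 0.3, seed=26)
    K = kinship(m)
    K2, labels = compress_kinship(K, 20)
    np.testing.assert_array_equal(K.values, K2.values)
    assert len(set(labels)) == 20


def test_compressed_scan_runs():
    rng = np.random.default_rng(27)
    m = random_matrix(40, 150, 0.3, seed=28)
    K = kinship(m)
    K2, _ = compress_kinship(K, 8)
    y = rng.standard_normal(40)
    scan = mlm_scan(y, m, K2)
    assert np.isfinite(scan.table.neglog10p).all()
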