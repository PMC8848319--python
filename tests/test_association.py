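import numpy as np
import pytest
from scipy import stats

from netepi import (
    GenotypeDataset,
    SnpRecord,
    SnpModel,
    ValidationError,
    adjust_phenotype,
    single_snp_assoc,
    interaction_test,
    PairScanner,
    scan_pairs,
    clump,
    compute_prs,
)
from netepi.association import AdjustedPhenotype, SeparationError, P_FLOOR
from netepi.io_formats import MISSING


def _dataset(columns, positions=None, chrom="1"):
    G = np.array(columns, dtype=np.int8).T
    n, m = G.shape
    snps = [
        SnpRecord(f"rs{j+1}", chrom, positions[j] if positions else (j + 1) * 1000)
        for j in range(m)
    ]
    return GenotypeDataset(
        sample_ids=[f"s{i}" for i in range(n)], snps=snps, genotypes=G,
        phenotype=np.zeros(n, dtype=np.int8),
    )


class TestAdjustPhenotype:
    def test_intercept_only_gives_centered_phenotype(self):
        y = np.array([0, 0, 1, 1, 1])
        res = adjust_phenotype(y)
        np.testing.assert_allclose(res.values, y - 0.6, atol=1e-8)

    def test_orthogonal_covariate_balanced_y(self):
        y = np.array([0, 1, 0, 1])
        cov = np.array([1.0, 1.0, -1.0, -1.0])[:, None]  # orthogonal to y
        res = adjust_phenotype(y, cov)
        np.testing.assert_allclose(np.abs(res.values), 0.5, atol=1e-6)

    def test_residuals_sum_to_zero_with_intercept(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=200)
        cov = rng.standard_normal((200, 3))
        res = adjust_phenotype(y, cov)
        assert abs(res.values.sum()) < 1e-6 * len(y)

    def test_matches_independent_newton_solver(self):
        """Coefficients recovered from the residuals match statsmodels GLM."""
        import statsmodels.api as sm

        y = np.array([0, 0, 0, 1, 0, 1, 1, 1], dtype=float)
        cov = np.array([-1.2, -0.8, -0.5, -0.1, 0.0, 0.4, 0.9, 1.5])[:, None]
        res = adjust_phenotype(y, cov)
        X = sm.add_constant(cov)
        fitted = sm.GLM(y, X, family=sm.families.Binomial()).fit().fittedvalues
        np.testing.assert_allclose(res.values, y - fitted, atol=1e-6)

    def test_perfect_separation_raises_named_error(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        cov = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])[:, None]
        with pytest.raises(SeparationError):
            adjust_phenotype(y, cov, covariate_names=["pc1"])

    def test_rank_deficiency_rejected(self):
        y = np.array([0, 1, 0, 1])
        cov = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValidationError, match="rank"):
            adjust_phenotype(y, cov)


class TestSingleSnpAssoc:
    def test_exact_linear_relationship_gives_floor_p(self):
        g = np.array([0, 1, 2, 0, 1, 2, 1, 0])
        beta, se, p = single_snp_assoc(g, g.astype(float))
        assert beta == pytest.approx(1.0)
        assert p == P_FLOOR

    def test_five_point_fixture_matches_normal_equations(self):
        g = np.array([0, 1, 2, 1, 0])
        y = np.array([0.2, -0.1, 0.7, 0.3, -0.4])
        X = np.column_stack([np.ones(5), g])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)[1]
        beta, se, p = single_snp_assoc(g, y)
        assert beta == pytest.approx(beta_oracle, abs=1e-10)
        # and the p-value against scipy's reference implementation
        lr = stats.linregress(g, y)
        assert p == pytest.approx(lr.pvalue, rel=1e-10)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, size=300)
        ps = [single_snp_assoc(g, rng.standard_normal(300))[2] for _ in range(1000)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_monomorphic_flagged_as_nan(self):
        beta, se, p = single_snp_assoc(np.zeros(10, dtype=int), np.random.default_rng(2).standard_normal(10))
        assert np.isnan(beta) and np.isnan(p)


class TestInteractionTest:
    def test_exact_product_relationship(self):
        rng = np.random.default_rng(3)
        gA = rng.binomial(2, 0.4, 100)
        gB = rng.binomial(2, 0.4, 100)
        res = interaction_test(gA, gB, (gA * gB).astype(float))
        assert res.beta3 == pytest.approx(1.0, abs=1e-8)
        assert res.p == P_FLOOR

    def test_six_sample_fixture_matches_normal_equations_oracle(self):
        gA = np.array([0, 1, 2, 0, 1, 2])
        gB = np.array([0, 0, 1, 1, 2, 2])
        y = np.array([0.1, -0.2, 0.5, 0.0, 0.3, 1.1])
        X = np.column_stack([np.ones(6), gA, gB, gA * gB])
        coefs = np.linalg.solve(X.T @ X, X.T @ y)
        res = interaction_test(gA, gB, y)
        assert res.beta3 == pytest.approx(coefs[3], abs=1e-10)
        resid = y - X @ coefs
        sigma2 = resid @ resid / (6 - 4)
        se3 = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[3, 3])
        assert res.se3 == pytest.approx(se3, abs=1e-10)

    def test_null_calibration_of_rejection_rate(self):
        """Over 2000 independent normal phenotypes, the fraction with
        p <= 0.05 sits in 0.05 +/- 0.015."""
        rng = np.random.default_rng(4)
        gA = rng.binomial(2, 0.3, 400).astype(np.int8)
        gB = rng.binomial(2, 0.3, 400).astype(np.int8)
        ds = _dataset([gA, gB])
        scanner = PairScanner(ds, [SnpModel("rs1", "rs2")])
        Y = rng.standard_normal((400, 2000))
        _, _, _, p = scanner.scan(Y)
        frac = (p[0] <= 0.05).mean()
        assert abs(frac - 0.05) < 0.015

    def test_orthogonal_extra_covariate_leaves_beta3_unchanged(self):
        rng = np.random.default_rng(5)
        gA = rng.binomial(2, 0.4, 500)
        gB = rng.binomial(2, 0.4, 500)
        y = rng.standard_normal(500)
        base = interaction_test(gA, gB, y)
        # orthogonalize a random covariate against [1, gA, gB, gA*gB, y]
        M = np.column_stack([np.ones(500), gA, gB, gA * gB, y])
        c = rng.standard_normal(500)
        c -= M @ np.linalg.lstsq(M, c, rcond=None)[0]
        adj = interaction_test(gA, gB, y, extra_covariates=c[:, None])
        assert adj.beta3 == pytest.approx(base.beta3, abs=1e-8)

    def test_collinear_design_flagged_degenerate(self):
        gA = np.array([0, 0, 0, 0, 2, 2, 2, 2])
        gB = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        # with gA binary 0/2, gA*gB is collinear once gB pattern repeats
        res = interaction_test(gA, np.zeros(8, dtype=int), np.random.default_rng(6).standard_normal(8))
        assert res.degenerate and res.p == 1.0

    def test_missing_genotypes_drop_complete_cases_only(self):
        rng = np.random.default_rng(7)
        gA = rng.binomial(2, 0.5, 60)
        gB = rng.binomial(2, 0.5, 60)
        y = rng.standard_normal(60)
        gA_miss = gA.copy()
        gA_miss[:5] = MISSING
        res = interaction_test(gA_miss, gB, y)
        ref = interaction_test(gA[5:], gB[5:], y[5:])
        assert res.n_used == 55
        assert res.beta3 == pytest.approx(ref.beta3, abs=1e-12)


class TestScanPairs:
    def test_store_threshold_retains_only_small_p(self):
        rng = np.random.default_rng(8)
        cols = [rng.binomial(2, 0.3, 500) for _ in range(6)]
        ds = _dataset(cols)
        y = AdjustedPhenotype(rng.standard_normal(500), [])
        models = [SnpModel("rs1", "rs2"), SnpModel("rs3", "rs4"), SnpModel("rs5", "rs6")]
        all_res, _ = scan_pairs(models, ds, y, store_threshold=1.0)
        assert len(all_res) == 3
        cut = sorted(r.p for r in all_res)[1]
        kept, _ = scan_pairs(models, ds, y, store_threshold=cut)
        assert len(kept) == 2
        assert [r.p for r in kept] == sorted(r.p for r in kept)

    def test_standard_mode_pair_count(self):
        from netepi.pipeline import _all_pairs_models
        rng = np.random.default_rng(9)
        ds = _dataset([rng.binomial(2, 0.3, 50) for _ in range(40)])
        assert len(_all_pairs_models(ds)) == 780


class TestClump:
    def test_close_correlated_snps_keep_smaller_p(self):
        rng = np.random.default_rng(10)
        a = rng.binomial(2, 0.4, 500).astype(np.int8)
        ds = _dataset([a, a], positions=[100_000, 110_000])
        kept = clump({"rs1": (0.1, 1e-6), "rs2": (0.1, 1e-3)}, ds)
        assert kept == ["rs1"]

    def test_distant_correlated_snps_both_kept(self):
        rng = np.random.default_rng(11)
        a = rng.binomial(2, 0.4, 500).astype(np.int8)
        ds = _dataset([a, a], positions=[100_000, 400_000])
        kept = clump({"rs1": (0.1, 1e-6), "rs2": (0.1, 1e-3)}, ds)
        assert set(kept) == {"rs1", "rs2"}

    def test_independent_snps_all_kept(self):
        rng = np.random.default_rng(12)
        ds = _dataset([rng.binomial(2, 0.4, 2000) for _ in range(5)],
                      positions=[1000, 2000, 3000, 4000, 5000])
        summary = {f"rs{j+1}": (0.0, 0.1 * (j + 1)) for j in range(5)}
        assert len(clump(summary, ds)) == 5

    def test_row_order_independent(self):
        rng = np.random.default_rng(13)
        a = rng.binomial(2, 0.4, 300).astype(np.int8)
        b = (2 - a).astype(np.int8)
        c = rng.binomial(2, 0.4, 300).astype(np.int8)
        ds = _dataset([a, b, c], positions=[1000, 2000, 3000])
        s1 = {"rs1": (0.1, 0.01), "rs2": (0.1, 0.02), "rs3": (0.1, 0.03)}
        s2 = dict(reversed(list(s1.items())))
        assert clump(s1, ds) == clump(s2, ds)


class TestComputePrs:
    def test_single_snp_unit_weight_recovers_dosage(self):
        ds = _dataset([[0, 1, 2, 1]])
        prs = compute_prs(ds, ["rs1"], {"rs1": 1.0})
        np.testing.assert_allclose(prs.scores, [0, 1, 2, 1])

    def test_opposite_weights_cancel(self):
        ds = _dataset([[2, 2], [2, 2]])
        prs = compute_prs(ds, ["rs1", "rs2"], {"rs1": 1.0, "rs2": -1.0})
        np.testing.assert_allclose(prs.scores, [0.0, 0.0])

    def test_missing_genotype_averages_over_observed(self):
        ds = _dataset([[2, 0], [MISSING, 1]])
        prs = compute_prs(ds, ["rs1", "rs2"], {"rs1": 1.0, "rs2": 1.0})
        assert prs.scores[0] == pytest.approx((2 + MISSING * 0 + 0) / 1 if False else 2.0)
        np.testing.assert_allclose(prs.scores, [2.0, 0.5])


class TestPrsAdjustmentProperty:
    def test_phantom_interaction_attenuated_by_prs(self):
        """Phantom epistasis: the causal SNP's minor allele occurs only on
        haplotypes carrying both tested minor alleles, so the tested pair's
        product term tags the main effect (E[gM | gA, gB] = gA*gB/2).
        Conditioning on the clumping+scoring PRS, which captures the causal
        main effect, makes the interaction p less significant in >= 90% of
        repetitions."""
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 1500
            a = rng.random((n, 2)) < 0.4
            b = rng.random((n, 2)) < 0.4
            gA, gB, gM = a.sum(1), b.sum(1), (a & b).sum(1)
            logit = -0.5 + 1.2 * gM
            yb = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(np.int8)
            ds = GenotypeDataset(
                [f"s{i}" for i in range(n)],
                [SnpRecord("rsM", "1", 10_000), SnpRecord("rsA", "1", 12_000),
                 SnpRecord("rsB", "1", 14_000)],
                np.column_stack([gM, gA, gB]).astype(np.int8), yb,
            )
            y = adjust_phenotype(yb).values
            un = interaction_test(gA, gB, y)
            summary = {}
            for j, sid in enumerate(ds.snp_ids):
                beta, _, p = single_snp_assoc(ds.genotypes[:, j], y)
                if np.isfinite(p):
                    summary[sid] = (beta, p)
            kept = clump(summary, ds)
            prs = compute_prs(ds, kept, {s: summary[s][0] for s in kept})
            ad = interaction_test(gA, gB, y, extra_covariates=prs.scores[:, None])
            if ad.p >= un.p:
                wins += 1
        assert wins >= int(0.9 * n_seeds)
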