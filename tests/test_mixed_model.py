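"""GRM arithmetic, REML recovery against a grid oracle, BLUP oracle, per-SNP OLS."""

import numpy as np
import pytest
from scipy import stats

from conftest import make_genotype_matrix
from ethnoprs.mixed_model import (
    GRM,
    KEig,
    FixedEffectEstimates,
    VarianceComponents,
    blup_snp_effects,
    compute_grm,
    per_snp_regression,
    reml_fit,
    reml_fit_partitioned,
    reml_loglik,
    standardize_genotypes,
)
from ethnoprs.synthetic import SimulationConfig, simulate_study


def trait_design(cohort, covs=("age", "sex", "height", "pack_years")):
    phen = cohort.phenotypes
    y = phen["trait"].to_numpy(dtype=float)
    Z = np.column_stack([np.ones(len(phen))] + [phen[c].to_numpy(dtype=float) for c in covs])
    return y, Z


class TestComputeGrm:
    def test_single_variant_hand_arithmetic(self):
        g = make_genotype_matrix(np.array([[0.0], [1.0], [2.0]]))
        X = standardize_genotypes(g)
        np.testing.assert_allclose(X.ravel(), [-np.sqrt(2), 0.0, np.sqrt(2)], atol=1e-12)
        k = compute_grm(g)
        np.testing.assert_allclose(np.diag(k.matrix), [2.0, 0.0, 2.0], atol=1e-12)

    def test_identical_rows_share_relatedness(self):
        rng = np.random.default_rng(0)
        vals = rng.binomial(2, 0.4, size=(4, 50)).astype(float)
        vals[1] = vals[0]
        k = compute_grm(make_genotype_matrix(vals)).matrix
        assert k[0, 1] == pytest.approx(k[0, 0], abs=1e-12)
        assert k[0, 1] == pytest.approx(k[1, 1], abs=1e-12)

    def test_diagonal_mean_near_one_under_hwe(self):
        rng = np.random.default_rng(1)
        freqs = rng.uniform(0.05, 0.5, 1000)
        vals = rng.binomial(2, freqs, size=(500, 1000)).astype(float)
        k = compute_grm(make_genotype_matrix(vals))
        assert 0.95 <= np.diag(k.matrix).mean() <= 1.05

    def test_monomorphic_excluded_with_warning(self):
        vals = np.column_stack([np.zeros(5), [0, 1, 2, 1, 0]])
        with pytest.warns(UserWarning, match="monomorphic"):
            k = compute_grm(make_genotype_matrix(vals))
        assert k.n_variants_used == 1


class TestRemlFit:
    def test_null_trait_heritability_at_boundary(self):
        cfg = SimulationConfig(n_variants=2000, n_causal=0, target_h2=0.0, covariate_effects={}, seed=21)
        cohort = simulate_study(cfg, n_samples=[1000], case_fractions=[0.3])[0]
        y, Z = trait_design(cohort)
        vc, _ = reml_fit(y, Z, compute_grm(cohort.genotypes))
        assert vc.h2 <= 0.05

    def test_parameter_recovery_moderate_h2(self):
        ests = []
        for seed in (31, 32, 33):
            cfg = SimulationConfig(n_variants=2000, n_causal=200, target_h2=0.4, covariate_effects={}, seed=seed)
            cohort = simulate_study(cfg, n_samples=[1000], case_fractions=[0.3])[0]
            y, Z = trait_design(cohort)
            vc, _ = reml_fit(y, Z, compute_grm(cohort.genotypes))
            ests.append(vc.h2)
        assert np.mean(ests) == pytest.approx(0.4, abs=0.1)

    def test_optimum_beats_grid_oracle(self, small_cohort):
        y, Z = trait_design(small_cohort)
        grm = compute_grm(small_cohort.genotypes)
        eig = KEig.from_grm(grm)
        vc, _ = reml_fit(y, Z, grm, eig=eig)
        vy = np.var(y)
        grid = np.linspace(1e-6, 2 * vy, 50)
        best_grid = max(
            reml_loglik(y, Z, eig, sg, se) for sg in grid for se in grid
        )
        assert vc.loglik >= best_grid - 1e-4

    def test_invariant_to_trait_shift_with_intercept(self, small_cohort):
        y, Z = trait_design(small_cohort)
        grm = compute_grm(small_cohort.genotypes)
        a, _ = reml_fit(y, Z, grm)
        b, _ = reml_fit(y + 100.0, Z, grm)
        assert a.sigma_g2 == pytest.approx(b.sigma_g2, rel=1e-6, abs=1e-10)
        assert a.sigma_e2 == pytest.approx(b.sigma_e2, rel=1e-6, abs=1e-10)

    def test_collinear_covariates_rejected(self, small_cohort):
        y, Z = trait_design(small_cohort)
        Zbad = np.column_stack([Z, Z[:, 1]])
        with pytest.raises(np.linalg.LinAlgError):
            reml_fit(y, Zbad, compute_grm(small_cohort.genotypes))


class TestRemlPartitioned:
    @staticmethod
    def _cohort_with_chrom_blocks(seed, h2, n=600, m=900):
        cfg = SimulationConfig(n_variants=m, n_causal=60, target_h2=h2, covariate_effects={}, seed=seed)
        cohort = simulate_study(cfg, n_samples=[n], case_fractions=[0.3])[0]
        return cohort

    def test_concentrated_component_recovers_share(self):
        # place every causal variant on the first third of the panel
        cfg = SimulationConfig(n_variants=900, n_causal=0, target_h2=0.0, covariate_effects={}, seed=41)
        from ethnoprs.synthetic import PopulationSpec, simulate_cohort

        rng = np.random.default_rng(41)
        idx = rng.choice(300, size=60, replace=False)
        pop = PopulationSpec("P", 600, 0.3, np.sort(idx), rng.standard_normal(60))
        cfg2 = SimulationConfig(n_variants=900, n_causal=60, target_h2=0.4, covariate_effects={}, seed=41)
        cohort = simulate_cohort(cfg2, [pop])[0]
        y, Z = trait_design(cohort)
        g = cohort.genotypes
        grms = [compute_grm(g.subset_variants(np.arange(s, s + 300))) for s in (0, 300, 600)]
        fit = reml_fit_partitioned(y, Z, grms)
        assert fit.shares[0] >= 0.8
        assert fit.shares.sum() == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_component_total_matches_single_fit(self):
        cohort = self._cohort_with_chrom_blocks(42, 0.4)
        y, Z = trait_design(cohort)
        grm = compute_grm(cohort.genotypes)
        single, _ = reml_fit(y, Z, grm)
        dup = reml_fit_partitioned(y, Z, [grm, grm])
        assert dup.sigma_c2.sum() == pytest.approx(single.sigma_g2, rel=0.05, abs=0.01)

    def test_null_simulation_components_near_zero(self):
        cohort = self._cohort_with_chrom_blocks(43, 0.0)
        y, Z = trait_design(cohort)
        g = cohort.genotypes
        grms = [compute_grm(g.subset_variants(np.arange(s, s + 300))) for s in (0, 300, 600)]
        fit = reml_fit_partitioned(y, Z, grms)
        assert np.all(fit.sigma_c2 <= 0.05 * np.var(y))

    def test_one_component_agrees_with_single_fit(self):
        cohort = self._cohort_with_chrom_blocks(44, 0.4, n=300, m=500)
        y, Z = trait_design(cohort)
        grm = compute_grm(cohort.genotypes)
        single, _ = reml_fit(y, Z, grm)
        multi = reml_fit_partitioned(y, Z, [grm])
        assert multi.sigma_c2[0] == pytest.approx(single.sigma_g2, abs=1e-8)
        assert multi.sigma_e2 == pytest.approx(single.sigma_e2, abs=1e-8)


class TestBlupSnpEffects:
    @staticmethod
    def _fixture(n=200, m=300, seed=51):
        cfg = SimulationConfig(n_variants=m, n_causal=30, target_h2=0.5, seed=seed)
        cohort = simulate_study(cfg, n_samples=[n], case_fractions=[0.3])[0]
        y, Z = trait_design(cohort)
        grm = compute_grm(cohort.genotypes)
        eig = KEig.from_grm(grm)
        fit = reml_fit(y, Z, grm, eig=eig)
        return cohort, y, Z, grm, eig, fit

    def test_zero_residual_gives_zero_scores(self):
        cohort, y, Z, grm, eig, _ = self._fixture()
        coef = np.array([1.0, 0.5, -0.2, 0.1, 0.05])
        y_exact = Z @ coef
        fit = (
            VarianceComponents(1.0, 1.0, 0.5, 0, 0, 0.0, True, 1),
            FixedEffectEstimates(coef, [f"z{i}" for i in range(5)]),
        )
        scores = blup_snp_effects(cohort.genotypes, grm, y_exact, Z, fit, eig=eig)
        np.testing.assert_allclose(scores.table["score"], 0.0, atol=1e-8)

    def test_matches_dense_inverse_oracle(self):
        cohort, y, Z, grm, eig, fit = self._fixture()
        assert fit[0].sigma_g2 > 0
        scores = blup_snp_effects(cohort.genotypes, grm, y, Z, fit, eig=eig)
        X = standardize_genotypes(cohort.genotypes)
        r = y - Z @ fit[1].coefficients
        # centered GRMs are singular, so K^-1 means the jittered inverse
        from ethnoprs.mixed_model import grm_jitter

        K_reg = grm.matrix + grm_jitter(eig.eigvals) * np.eye(grm.matrix.shape[0])
        oracle = X.T @ np.linalg.inv(K_reg) @ r / fit[0].sigma_g2
        np.testing.assert_allclose(scores.table["score"], oracle, rtol=1e-8)

    def test_sigma_scaling_preserves_ranking(self):
        cohort, y, Z, grm, eig, fit = self._fixture()
        vc, fe = fit
        scaled = (
            VarianceComponents(3.0 * vc.sigma_g2, vc.sigma_e2, vc.h2, 0, 0, 0.0, True, 1),
            fe,
        )
        a = blup_snp_effects(cohort.genotypes, grm, y, Z, fit, eig=eig).table
        b = blup_snp_effects(cohort.genotypes, grm, y, Z, scaled, eig=eig).table
        np.testing.assert_allclose(b["score"] * 3.0, a["score"], rtol=1e-10)
        assert list(a.sort_values("score")["id"]) == list(b.sort_values("score")["id"])

    def test_boundary_sigma_rejected(self):
        cohort, y, Z, grm, eig, fit = self._fixture()
        boundary = (
            VarianceComponents(0.0, 1.0, 0.0, 0, 0, 0.0, True, 1),
            fit[1],
        )
        with pytest.raises(ValueError, match="boundary"):
            blup_snp_effects(cohort.genotypes, grm, y, Z, boundary, eig=eig)


class TestPerSnpRegression:
    def test_worked_fixture_matches_normal_equations(self):
        g = make_genotype_matrix(np.array([[0.0], [1.0], [2.0], [1.0], [0.0]]))
        y = np.array([0.2, 1.1, 2.3, 0.9, -0.1])
        Z = np.column_stack([np.ones(5), [50, 55, 60, 45, 52]])
        res = per_snp_regression(g, y, Z)
        A = np.column_stack([Z, g.values[:, 0]])
        beta_full = np.linalg.solve(A.T @ A, A.T @ y)
        resid = y - A @ beta_full
        sigma2 = resid @ resid / (5 - 3)
        cov = sigma2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(cov[2, 2])
        t = beta_full[2] / se
        p = 2 * stats.t.sf(abs(t), 5 - 3)
        assert res.loc[0, "beta"] == pytest.approx(beta_full[2], abs=1e-10)
        assert res.loc[0, "se"] == pytest.approx(se, abs=1e-10)
        assert res.loc[0, "p"] == pytest.approx(p, abs=1e-10)

    def test_orthogonal_genotype_gives_null_effect(self):
        # genotype residualized against Z is orthogonal to residualized y
        Z = np.column_stack([np.ones(6)])
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        geno = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])  # orthogonal to y after centering
        g = make_genotype_matrix(geno.reshape(-1, 1))
        res = per_snp_regression(g, y, Z)
        assert res.loc[0, "beta"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc[0, "p"] == pytest.approx(1.0, abs=1e-10)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(61)
        vals = rng.binomial(2, 0.3, size=(300, 2000)).astype(float)
        g = make_genotype_matrix(vals)
        y = rng.standard_normal(300)
        Z = np.ones((300, 1))
        res = per_snp_regression(g, y, Z)
        frac = (res["p"] < 0.05).mean()
        assert 0.04 <= frac <= 0.06

    def test_collinear_covariates_named(self):
        g = make_genotype_matrix(np.array([[0.0], [1.0], [2.0], [1.0]]))
        Z = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            per_snp_regression(g, np.zeros(4), Z)
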