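"""Penalized logistic fits against IRLS/stationarity oracles, AUC, CV machinery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ethnoprs.prediction import (
    CVPlan,
    PenaltySpec,
    auc,
    cross_validate_pipeline,
    external_validate,
    fit_penalized_logistic,
    lambda_grid,
    model_from_dict,
    model_to_dict,
    nested_cv_tune,
    predict_risk,
)
from ethnoprs.synthetic import SimulationConfig, simulate_study


def logistic_fixture(n=200, d=10, seed=3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    beta = rng.normal(0, 0.5, d)
    p = 1 / (1 + np.exp(-(0.2 + X @ beta)))
    y = rng.binomial(1, p).astype(float)
    mask = np.zeros(d, dtype=bool)
    mask[d // 2 :] = True  # back half is the "SNP" block
    return X, y, mask


class TestFitPenalizedLogistic:
    def test_lambda_zero_matches_irls_mle(self):
        X, y, mask = logistic_fixture()
        model = fit_penalized_logistic(X, y, PenaltySpec("lasso", 0.0), mask, tol=1e-10)
        sm_fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0, method="newton", tol=1e-12)
        ours = np.concatenate([[model.intercept], model.clinical_coef, model.variant_coef])
        # our layout keeps clinical columns before variant columns; here the
        # natural order already satisfies that
        assert np.max(np.abs(ours - sm_fit.params)) < 1e-5

    def test_huge_lambda_lasso_zeroes_snp_block_only(self):
        X, y, mask = logistic_fixture()
        model = fit_penalized_logistic(X, y, PenaltySpec("lasso", 1e6), mask, tol=1e-10)
        assert np.all(model.variant_coef == 0.0)
        reduced = sm.Logit(y, sm.add_constant(X[:, ~mask])).fit(disp=0, method="newton", tol=1e-12)
        ours = np.concatenate([[model.intercept], model.clinical_coef])
        assert np.max(np.abs(ours - reduced.params)) < 1e-5

    def test_ridge_stationarity(self):
        X, y, mask = logistic_fixture()
        # pre-standardize so the internal scale matches the gradient check
        Xs = (X - X.mean(0)) / X.std(0)
        lam = 0.05
        model = fit_penalized_logistic(Xs, y, PenaltySpec("ridge", lam), mask, tol=1e-12)
        beta = np.concatenate([model.clinical_coef, model.variant_coef])
        eta = model.intercept + Xs @ beta
        p = 1 / (1 + np.exp(-eta))
        grad_beta = Xs.T @ (p - y) / y.size + lam * np.where(mask, beta, 0.0)
        grad_int = np.mean(p - y)
        assert max(np.max(np.abs(grad_beta)), abs(grad_int)) < 1e-6

    def test_objective_monotone_every_sweep(self):
        X, y, mask = logistic_fixture(seed=9)
        for fam, lam in (("lasso", 0.02), ("ridge", 0.1), ("elastic_net", 0.05)):
            model = fit_penalized_logistic(X, y, PenaltySpec(fam, lam), mask)
            diffs = np.diff(model.objective_history)
            assert np.all(diffs <= 1e-12), fam

    def test_lasso_path_sparsity_monotone(self):
        X, y, mask = logistic_fixture(seed=11)
        lams = lambda_grid(X, y, mask, "lasso", n_lambda=12)
        nnz = []
        for lam in lams:  # descending
            m = fit_penalized_logistic(X, y, PenaltySpec("lasso", float(lam)), mask)
            nnz.append(int(np.sum(m.variant_coef != 0)))
        assert nnz == sorted(nnz)  # sparsest at the largest lambda
        assert nnz[0] == 0  # lambda_max zeroes the whole penalized block

    def test_single_class_rejected(self):
        X, _, mask = logistic_fixture()
        with pytest.raises(ValueError, match="class"):
            fit_penalized_logistic(X, np.zeros(len(X)), PenaltySpec("ridge", 0.1), mask)


class TestPredictRisk:
    def test_zero_model_gives_half(self):
        X, y, mask = logistic_fixture()
        m = fit_penalized_logistic(X, y, PenaltySpec("ridge", 0.1), mask)
        m.intercept = 0.0
        m.clinical_coef[:] = 0.0
        m.variant_coef[:] = 0.0
        np.testing.assert_allclose(predict_risk(m, X), 0.5)

    def test_hand_computed_probability(self):
        X, y, mask = logistic_fixture(d=2)
        m = fit_penalized_logistic(X, y, PenaltySpec("ridge", 0.1), mask)
        m.intercept = 0.5
        m.clinical_coef = np.array([1.0])
        m.variant_coef = np.array([0.0])
        x = np.array([[1.0, 0.0]])
        assert predict_risk(m, x)[0] == pytest.approx(1 / (1 + np.exp(-1.5)))

    def test_extreme_linear_predictor_limits(self):
        X, y, mask = logistic_fixture(d=2)
        m = fit_penalized_logistic(X, y, PenaltySpec("ridge", 0.1), mask)
        m.intercept = 0.0
        m.clinical_coef = np.array([1.0])
        m.variant_coef = np.array([0.0])
        big = np.array([[1e4, 0.0], [-1e4, 0.0]])
        p = predict_risk(m, big)
        assert p[0] == pytest.approx(1.0) and p[1] == pytest.approx(0.0)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_worked_case(self):
        assert auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_all_ties_is_half(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            auc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n = rng.integers(6, 30)
            scores = rng.integers(0, 5, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            cases = scores[labels == 1]
            controls = scores[labels == 0]
            wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
            assert auc(scores, labels) == pytest.approx(wins / (len(cases) * len(controls)))


def tiny_cohort(seed=33, n=300, h2=0.5, overlap=1.0, fst=0.05, n_pops=1, m=400, n_causal=40):
    cfg = SimulationConfig(
        n_variants=m,
        n_causal=n_causal,
        target_h2=h2,
        fst=fst,
        cross_population_causal_overlap=overlap,
        seed=seed,
    )
    return simulate_study(cfg, n_samples=[n] * n_pops, case_fractions=[0.3] * n_pops)


class TestNestedCvTune:
    def test_single_grid_point_selected(self):
        cohort = tiny_cohort()[0]
        plan = CVPlan(p_grid=(20,), penalty_grid=("ridge",), n_lambda=3, seed=4)
        from ethnoprs.prediction import make_blup_provider

        sel, table = nested_cv_tune(
            cohort.genotypes, cohort.phenotypes, plan, make_blup_provider("abs_blup", 20)
        )
        assert sel["p"] == 20 and sel["penalty"] == "ridge"
        assert len(table) == 3

    def test_deterministic_given_seed(self):
        cohort = tiny_cohort()[0]
        plan = CVPlan(p_grid=(10, 20), penalty_grid=("ridge",), n_lambda=3, seed=4)
        from ethnoprs.prediction import make_blup_provider

        runs = [
            nested_cv_tune(
                cohort.genotypes, cohort.phenotypes, plan, make_blup_provider("abs_blup", 20)
            )
            for _ in range(2)
        ]
        assert runs[0][0] == runs[1][0]
        pd.testing.assert_frame_equal(runs[0][1], runs[1][1])


class TestCrossValidatePipeline:
    def test_clinical_signal_detected_and_genetics_add_signal(self):
        cohort = tiny_cohort(seed=55, n=500, h2=0.6, m=500, n_causal=30)[0]
        plan = CVPlan(p_grid=(30,), penalty_grid=("ridge",), n_lambda=5, seed=2)
        res = cross_validate_pipeline(cohort.genotypes, cohort.phenotypes, plan)
        assert 0.5 < res.mean_auc <= 1.0
        assert len(res.fold_aucs) == 5
        assert all(0 <= a <= 1 for a in res.fold_aucs)

    def test_screening_blind_to_held_out_samples(self):
        cohort = tiny_cohort(seed=56, n=300, m=300, n_causal=30)[0]
        plan = CVPlan(p_grid=(20,), penalty_grid=("ridge",), n_lambda=3, seed=7)
        res1 = cross_validate_pipeline(cohort.genotypes, cohort.phenotypes, plan)
        # permute fold 0's held-out trait values; fold 0's screening must not move
        test_idx = np.flatnonzero(res1.fold_assignments == 0)
        phen2 = cohort.phenotypes.copy()
        rng = np.random.default_rng(0)
        phen2.loc[test_idx, "trait"] = (
            phen2.loc[test_idx, "trait"].to_numpy()[rng.permutation(len(test_idx))]
        )
        res2 = cross_validate_pipeline(cohort.genotypes, phen2, plan)
        assert res1.screening_lists[0].variant_ids == res2.screening_lists[0].variant_ids


class TestExternalValidate:
    def test_self_validation_matches_in_sample_auc(self):
        cohort = tiny_cohort(seed=57)[0]
        plan = CVPlan(p_grid=(20,), penalty_grid=("ridge",), n_lambda=3, seed=1)
        res = cross_validate_pipeline(cohort.genotypes, cohort.phenotypes, plan)
        model = res.models[0]
        ext = external_validate(model, cohort.genotypes, cohort.phenotypes)
        from ethnoprs.prediction import _design

        X, _ = _design(cohort.phenotypes, cohort.genotypes, model.variant_ids, model.clinical_names)
        in_sample = auc(predict_risk(model, X), cohort.phenotypes["status"].to_numpy())
        assert ext.auc == pytest.approx(in_sample, abs=1e-12)
        assert ext.n_matched == ext.n_modeled

    def test_unmatched_variants_logged_and_zeroed(self):
        cohort = tiny_cohort(seed=58)[0]
        plan = CVPlan(p_grid=(10,), penalty_grid=("ridge",), n_lambda=3, seed=1)
        res = cross_validate_pipeline(cohort.genotypes, cohort.phenotypes, plan)
        model = res.models[0]
        model.variant_ids[0] = "rs_not_there"
        with pytest.warns(None) if False else np.errstate():
            ext = external_validate(model, cohort.genotypes, cohort.phenotypes)
        assert ext.n_matched == ext.n_modeled - 1
        assert list(ext.unmatched_log["reason"]) == ["absent"]

    def test_serialization_round_trip_preserves_predictions(self):
        cohort = tiny_cohort(seed=59)[0]
        plan = CVPlan(p_grid=(10,), penalty_grid=("lasso",), n_lambda=3, seed=1)
        res = cross_validate_pipeline(cohort.genotypes, cohort.phenotypes, plan)
        model = res.models[0]
        clone = model_from_dict(model_to_dict(model))
        a = external_validate(model, cohort.genotypes, cohort.phenotypes).auc
        b = external_validate(clone, cohort.genotypes, cohort.phenotypes).auc
        assert a == b
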