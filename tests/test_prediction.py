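"""Shrinkage regression, three-stage CV, permutations, moderation."""

import numpy as np
import pandas as pd
import pytest

from stopnet.prediction import (
    compare_models,
    cv_predict_scores,
    independence_check,
    ledoit_wolf_shrinkage,
    model_comparison,
    moderation_analysis,
    permutation_pvalue,
    repartition_distribution,
    shrinkage_mlr_fit,
    structure_coefficients,
)
from stopnet.simulate import cohort_feature_table, generate_cohort


@pytest.fixture(scope="module")
def linear_problem():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((80, 6))
    w = rng.standard_normal(6)
    y = X @ w + 0.05 * rng.standard_normal(80)
    return X, y, w


@pytest.fixture(scope="module")
def feature_cohort():
    coh = generate_cohort(60, seed=100)
    ft = cohort_feature_table(coh, seed=101)
    return ft


class TestShrinkageFit:
    def test_matches_sklearn_intensity(self):
        from sklearn.covariance import ledoit_wolf

        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 8)) @ rng.standard_normal((8, 8))
        _, sk_gamma = ledoit_wolf(X)
        gamma, _ = ledoit_wolf_shrinkage(X - X.mean(0))
        assert gamma == pytest.approx(sk_gamma, rel=1e-10)

    def test_gamma_zero_reduces_to_ols(self, linear_problem):
        X, y, _ = linear_problem
        w_s, b_s, _ = shrinkage_mlr_fit(X, y, gamma=0.0)
        Xd = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(w_s, beta[1:], atol=1e-8)
        assert b_s == pytest.approx(beta[0], abs=1e-8)

    def test_finite_when_p_exceeds_n(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 200))
        y = rng.standard_normal(30)
        w, b, gamma = shrinkage_mlr_fit(X, y)
        assert np.isfinite(w).all() and np.isfinite(b)
        assert 0 < gamma <= 1

    def test_weight_recovery_large_n(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((16000, 5))
        w_true = np.array([1.5, -2.0, 0.8, 3.0, -1.0])
        y = X @ w_true + 0.05 * rng.standard_normal(16000)
        w, _, _ = shrinkage_mlr_fit(X, y)
        assert np.max(np.abs(w - w_true) / np.abs(w_true)) < 0.05

    def test_zero_variance_y_rejected(self):
        with pytest.raises(ValueError):
            shrinkage_mlr_fit(np.random.default_rng(0).standard_normal((20, 3)),
                              np.ones(20))


class TestCvPredictScores:
    def test_linear_signal_recovered(self, linear_problem):
        X, y, _ = linear_problem
        res = cv_predict_scores(X, y, k=10, seed=1)
        assert res.observed_r > 0.95

    def test_null_r_near_zero(self):
        rng = np.random.default_rng(4)
        rs = [
            cv_predict_scores(
                rng.standard_normal((60, 5)), rng.standard_normal(60), k=10, seed=i
            ).observed_r
            for i in range(40)
        ]
        assert abs(np.mean(rs)) < 0.1

    def test_no_leakage_from_held_out_targets(self, linear_problem):
        """Scores for a fold are identical when that fold's y is perturbed."""
        X, y, _ = linear_problem
        res = cv_predict_scores(X, y, k=10, seed=7)
        rng = np.random.default_rng(8)
        # find the test fold containing subject 0 by perturbing y[0]
        y2 = y.copy()
        y2[0] += 1000.0
        res2 = cv_predict_scores(X, y2, k=10, seed=7)
        assert res2.subject_scores[0] == res.subject_scores[0]

    def test_each_subject_scored_once(self, linear_problem):
        X, y, _ = linear_problem
        res = cv_predict_scores(X, y, k=10, seed=2)
        assert np.isfinite(res.subject_scores).all()
        assert len(res.gamma_per_fold) == 10

    def test_covariate_residualization_changes_scores(self, linear_problem):
        X, y, _ = linear_problem
        C = np.linspace(0, 1, len(y))[:, None]
        res_plain = cv_predict_scores(X, y, k=10, seed=3)
        res_cov = cv_predict_scores(X, y + 10 * C[:, 0], covariates=C, k=10, seed=3)
        # covariate-adjusted y matches the covariate-free problem closely
        assert abs(res_cov.observed_r - res_plain.observed_r) < 0.1

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            cv_predict_scores(np.ones((10, 2)), np.arange(10.0), k=10)


class TestPermutationPvalue:
    def test_strong_signal_attains_minimum(self, linear_problem):
        X, y, _ = linear_problem
        res = cv_predict_scores(X, y, k=10, seed=1)
        p, _ = permutation_pvalue(X, y, n_perm=99, seed=1, observed_r=res.observed_r)
        assert p == pytest.approx(1.0 / 100.0)

    def test_invariant_to_feature_column_order(self, linear_problem):
        X, y, _ = linear_problem
        r1 = cv_predict_scores(X, y, k=10, seed=5).observed_r
        r2 = cv_predict_scores(X[:, ::-1], y, k=10, seed=5).observed_r
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_minimum_permutations_enforced(self, linear_problem):
        X, y, _ = linear_problem
        with pytest.raises(ValueError):
            permutation_pvalue(X, y, n_perm=10)


class TestRepartition:
    def test_sd_shrinks_with_sample_size(self):
        rng = np.random.default_rng(9)
        sds = []
        for n in (40, 160):
            X = rng.standard_normal((n, 5))
            y = X @ np.array([1.0, 0.5, 0, 0, -0.5]) + 1.5 * rng.standard_normal(n)
            sds.append(repartition_distribution(X, y, n_repart=40, k=10, seed=2).std())
        assert sds[1] < sds[0]

    def test_mean_close_to_single_run(self, linear_problem):
        X, y, _ = linear_problem
        dist = repartition_distribution(X, y, n_repart=30, k=10, seed=3)
        single = cv_predict_scores(X, y, k=10, seed=11).observed_r
        assert abs(dist.mean() - single) < 3 * dist.std() + 0.02


class TestCompareModels:
    def test_identical_models_zero_difference(self):
        r = np.full(50, 0.3)
        null = np.zeros((99, 2))
        diff, p = compare_models(r, r, null)
        assert diff == 0.0
        assert p > 0.5

    def test_antisymmetric(self):
        rng = np.random.default_rng(10)
        a, b = rng.uniform(0, 0.5, 50), rng.uniform(0, 0.5, 50)
        null = rng.standard_normal((99, 2)) * 0.01
        d_ab, _ = compare_models(a, b, null)
        d_ba, _ = compare_models(b, a, null[:, ::-1])
        assert d_ab == pytest.approx(-d_ba)

    def test_informative_beats_noise_features(self):
        rng = np.random.default_rng(11)
        n = 80
        X_good = rng.standard_normal((n, 5))
        y = X_good @ np.array([1, 1, 0.5, 0, 0.0]) + 0.8 * rng.standard_normal(n)
        X_noise = rng.standard_normal((n, 5))
        out = model_comparison(X_good, X_noise, y, n_repart=30, n_perm=99,
                               n_repart_null=10, k=10, seed=12)
        assert out["difference"] > 0.3
        assert out["p"] <= 1.0 / (99 + 1) + 1e-12  # attainable minimum


class TestStructureCoefficients:
    def test_feature_equal_to_scores(self):
        rng = np.random.default_rng(12)
        s = rng.standard_normal(50)
        X = np.column_stack([s, rng.standard_normal(50)])
        out = structure_coefficients(X, s)
        assert out.iloc[0]["r"] == pytest.approx(1.0)
        assert abs(out.iloc[1]["r"]) < 0.4

    def test_zero_variance_flagged(self):
        out = structure_coefficients(np.ones((30, 1)),
                                     np.random.default_rng(0).standard_normal(30))
        assert out.iloc[0]["flag"] == "zero variance"

    def test_generative_drivers_rank_highest(self, feature_cohort):
        ft = feature_cohort
        y = ft["subjects"]["ssrt_true_ms"].to_numpy()
        X = ft["cppi"]
        res = cv_predict_scores(X.to_numpy(), y, k=10, seed=0)
        out = structure_coefficients(X, res.subject_scores)
        # injected pairs (ic00-ic01, ic02-ic03) carry the signal
        top2 = out["r"].abs().nlargest(2).index
        assert set(top2) == {"ic00-ic01", "ic02-ic03"}


class TestModeration:
    def test_scores_only_effect(self):
        rng = np.random.default_rng(13)
        n = 150
        s = rng.standard_normal(n)
        age = rng.uniform(18, 88, n)
        y = 2.0 * s + rng.standard_normal(n)
        m = moderation_analysis(s, age, y)
        assert m.table.loc["subject_scores", "p"] < 0.001
        assert m.table.loc["scores_x_age", "p"] > 0.01

    def test_interaction_detected_when_injected(self):
        rng = np.random.default_rng(14)
        n = 150
        s = rng.standard_normal(n)
        age = rng.uniform(18, 88, n)
        ac = (age - age.mean()) / age.std()
        y = s + 1.0 * s * ac + 0.8 * rng.standard_normal(n)
        m = moderation_analysis(s, age, y)
        assert m.table.loc["scores_x_age", "p"] < 0.01

    def test_pure_noise_y_nothing_significant(self):
        rng = np.random.default_rng(15)
        hits = 0
        for i in range(40):
            s = rng.standard_normal(80)
            age = rng.uniform(18, 88, 80)
            y = rng.standard_normal(80)
            m = moderation_analysis(s, age, y)
            hits += int(m.table.loc["scores_x_age", "p"] < 0.05)
        assert hits <= 6

    def test_collinear_design_rejected(self):
        s = np.arange(30.0)
        with pytest.raises(np.linalg.LinAlgError):
            moderation_analysis(s, s, np.random.default_rng(0).standard_normal(30))


class TestIndependence:
    def test_identical_scores(self):
        s = np.random.default_rng(16).standard_normal(40)
        r, _ = independence_check(s, s)
        assert r == pytest.approx(1.0)

    def test_independent_channels_uncorrelated(self, feature_cohort):
        ft = feature_cohort
        y = ft["subjects"]["ssrt_true_ms"].to_numpy()
        # predict from activity and from spontaneous (y-independent) features
        s_act = cv_predict_scores(ft["activity"].to_numpy(), y, k=10, seed=1).subject_scores
        s_spo = cv_predict_scores(ft["spontaneous"].to_numpy(), y, k=10, seed=2).subject_scores
        r, p = independence_check(s_act, s_spo)
        assert abs(r) < 0.35

    def test_shared_driver_induces_correlation(self):
        rng = np.random.default_rng(17)
        n = 100
        z = rng.standard_normal(n)
        y = z + 0.5 * rng.standard_normal(n)
        Xa = np.column_stack([z + 0.3 * rng.standard_normal(n) for _ in range(4)])
        Xb = np.column_stack([z + 0.3 * rng.standard_normal(n) for _ in range(4)])
        sa = cv_predict_scores(Xa, y, k=10, seed=3).subject_scores
        sb = cv_predict_scores(Xb, y, k=10, seed=4).subject_scores
        r, p = independence_check(sa, sb)
        assert r > 0.5 and p < 0.001
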