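import itertools

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st
from scipy.optimize import minimize

from facebmi.exceptions import ValidationError
from facebmi.models import (
    FittedModel,
    ModelSpec,
    elastic_net_objective,
    exclude_outliers,
    fit_elastic_net,
    fit_ols,
    fit_svr_rbf,
    inverse_outcome,
    predict,
    rbf_kernel,
    transform_outcome,
    tune_elastic_net,
)


class TestOutcomeTransform:
    def test_reciprocal_values(self):
        np.testing.assert_allclose(transform_outcome([25.0]), [0.04])
        assert inverse_outcome(transform_outcome([23.24]))[0] == pytest.approx(23.24)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            transform_outcome([25.0, 0.0])

    def test_synthetic_population_normalized_by_reciprocal(self):
        """Raw synthetic BMI fails Shapiro-Wilk at study size; 1/BMI passes."""
        from scipy.stats import shapiro

        from facebmi.synthetic import SyntheticConfig, sample_population

        subs, _ = sample_population(SyntheticConfig(n_subjects=526, seed=42))
        bmi = np.array([s.bmi for s in subs])
        assert shapiro(bmi).pvalue < 0.05
        assert shapiro(transform_outcome(bmi)).pvalue > 0.05


class TestOutlierExclusion:
    def test_three_sd_rule(self):
        # tight cluster around 23 (sd ~2.45) plus two candidates
        y = np.concatenate([np.repeat([20.0, 23.0, 26.0], 100), [36.0, 30.0]])
        keep, summary = exclude_outliers(y)
        assert not keep[-2]  # 36 lies beyond mean + 3 sd
        assert keep[-1]  # 30 does not
        assert summary.n_excluded == 1
        assert summary.mean_excluded_bmi == pytest.approx(36.0)

    def test_all_equal_excludes_none(self):
        keep, summary = exclude_outliers(np.full(10, 22.0))
        assert keep.all() and summary.n_excluded == 0

    def test_study_sized_population_excludes_a_handful_of_overweight(self):
        """At n~526 the skewed BMI law loses a few high-BMI subjects to the
        3-SD rule, and only high-BMI ones."""
        from facebmi.synthetic import SyntheticConfig, sample_population

        subs, _ = sample_population(SyntheticConfig(n_subjects=526, seed=8))
        bmi = np.array([s.bmi for s in subs])
        keep, summary = exclude_outliers(bmi)
        assert 1 <= summary.n_excluded <= 20
        assert np.all(bmi[~keep] > bmi.mean())  # all excluded are overweight


class TestOLS:
    def test_exact_linear_fit(self):
        x = np.arange(10.0)[:, None]
        model = fit_ols(x, 2 * x[:, 0] + 1)
        assert model.intercept == pytest.approx(1.0)
        assert model.coef[0] == pytest.approx(2.0)
        assert predict(model, [[3.0]])[0] == pytest.approx(7.0)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        model = fit_ols(X, y)
        D = np.column_stack([np.ones(20), X])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        np.testing.assert_allclose(model.params, beta, atol=1e-10)
        resid = y - predict(model, X)
        np.testing.assert_allclose(X.T @ resid, 0.0, atol=1e-8)

    def test_duplicated_column_rejected(self, rng):
        x = rng.normal(size=(10, 1))
        with pytest.raises(ValidationError):
            fit_ols(np.hstack([x, x]), rng.normal(size=10))


class TestElasticNet:
    def test_zero_penalties_equal_ols(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ [1.0, -2.0, 0.5, 0.0] + rng.normal(size=30) * 0.1
        enet = fit_elastic_net(X, y, 0.0, 0.0)
        ols = fit_ols(X, y)
        np.testing.assert_allclose(predict(enet, X), predict(ols, X), atol=1e-6)

    def test_huge_l1_zeroes_everything(self, rng):
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        model = fit_elastic_net(X, y, 1e6, 0.0)
        np.testing.assert_array_equal(model.coef, 0.0)
        np.testing.assert_allclose(predict(model, X), y.mean())

    def test_matches_brute_force_grid_minimizer(self, rng):
        """p=2 toy problem against a dense objective grid over beta."""
        X = rng.normal(size=(15, 2))
        X = (X - X.mean(0)) / X.std(0)
        y = X @ [1.2, -0.7] + rng.normal(size=15) * 0.3
        yc = y - y.mean()
        l1, l2 = 3.0, 2.0
        grid = np.linspace(-2, 2, 801)
        b1, b2 = np.meshgrid(grid, grid, indexing="ij")
        B = np.stack([b1.ravel(), b2.ravel()])
        rss = ((yc[:, None] - X @ B) ** 2).sum(0)
        obj = rss + l2 * (B**2).sum(0) + l1 * np.abs(B).sum(0)
        best = obj.min()
        model = fit_elastic_net(X, y, l1, l2, standardize=False)
        ours = elastic_net_objective(X, yc, 0.0, model.coef, l1, l2)
        assert ours <= best + 1e-4

    def test_ridge_limit_matches_closed_form(self, rng):
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        Xs = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()
        l2 = 7.5
        beta_ridge = np.linalg.solve(Xs.T @ Xs + l2 * np.eye(5), Xs.T @ yc)
        model = fit_elastic_net(X, y, 0.0, l2)
        np.testing.assert_allclose(model.coef, beta_ridge, atol=1e-6)

    def test_lasso_limit_produces_exact_zeros(self, rng):
        X = rng.normal(size=(40, 6))
        y = X[:, 0] * 2.0 + rng.normal(size=40) * 0.5
        model = fit_elastic_net(X, y, 30.0, 0.0)
        assert np.sum(model.coef == 0.0) >= 1
        assert model.coef[0] != 0.0

    def test_matches_sklearn_naive_objective_mapping(self, rng):
        """Independent oracle: sklearn's ElasticNet minimises
        1/(2n)||r||^2 + alpha(rho||b||_1 + (1-rho)/2 ||b||^2); multiplying by
        2n maps (alpha, rho) onto (lambda1, lambda2) = (2n alpha rho,
        n alpha (1-rho))."""
        from sklearn.linear_model import ElasticNet

        X = rng.normal(size=(50, 4))
        X = (X - X.mean(0)) / X.std(0)
        y = X @ [1.0, -0.5, 0.0, 0.25] + rng.normal(size=50) * 0.2
        n = len(y)
        alpha, rho = 0.05, 0.4
        sk = ElasticNet(alpha=alpha, l1_ratio=rho, fit_intercept=True,
                        tol=1e-12, max_iter=100000).fit(X, y)
        l1, l2 = 2 * n * alpha * rho, n * alpha * (1 - rho)
        ours = fit_elastic_net(X, y, l1, l2, standardize=False)
        np.testing.assert_allclose(ours.coef, sk.coef_, atol=1e-6)

    def test_objective_not_worse_than_zero_or_ols(self, rng):
        X = rng.normal(size=(30, 3))
        X = (X - X.mean(0)) / X.std(0)
        y = rng.normal(size=30)
        yc = y - y.mean()
        for l1, l2 in [(0.0, 0.0), (1.0, 0.0), (0.0, 5.0), (2.0, 3.0)]:
            model = fit_elastic_net(X, y, l1, l2, standardize=False)
            at_fit = elastic_net_objective(X, yc, 0.0, model.coef, l1, l2)
            at_zero = elastic_net_objective(X, yc, 0.0, np.zeros(3), l1, l2)
            ols_beta = fit_ols(X, y).coef
            at_ols = elastic_net_objective(X, yc, 0.0, ols_beta, l1, l2)
            assert at_fit <= at_zero + 1e-10
            assert at_fit <= at_ols + 1e-10

    def test_predictions_invariant_to_feature_rescaling(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        model_a = fit_elastic_net(X, y, 2.0, 1.0, standardize=True)
        model_b = fit_elastic_net(X * [10.0, 0.1, 3.0] + [5, -2, 0], y, 2.0, 1.0,
                                  standardize=True)
        Xnew = rng.normal(size=(5, 3))
        np.testing.assert_allclose(
            predict(model_a, Xnew),
            predict(model_b, Xnew * [10.0, 0.1, 3.0] + [5, -2, 0]),
            atol=1e-8,
        )


class TestTuning:
    def test_noise_outcome_selects_shrinkage(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60)  # pure noise
        l1, l2 = tune_elastic_net(X, y, [0.0, 1.0, 10.0, 100.0, 1000.0],
                                  inner_k=5, inner_repeats=2, seed=3)
        chosen = fit_elastic_net(X, y, l1, l2)
        unpenalized = fit_elastic_net(X, y, 0.0, 0.0)
        assert np.linalg.norm(chosen.coef) <= np.linalg.norm(unpenalized.coef) + 1e-12

    def test_strong_signal_beats_max_shrinkage_corner(self, rng):
        from facebmi.cv import r_squared, stratified_folds

        X = rng.normal(size=(60, 3))
        y = X @ [2.0, -1.0, 0.5] + rng.normal(size=60) * 0.05
        grid = [0.0, 10.0, 1000.0]
        l1, l2 = tune_elastic_net(X, y, grid, inner_k=5, inner_repeats=2, seed=3)

        def inner_score(a, b):
            plan = stratified_folds(y, k=5, seed=99)
            scores = []
            for f in range(5):
                te = plan.assignments == f
                m = fit_elastic_net(X[~te], y[~te], a, b)
                scores.append(r_squared(y[te], predict(m, X[te])))
            return np.mean(scores)

        assert inner_score(l1, l2) >= inner_score(1000.0, 1000.0) - 1e-9

    def test_boundary_lambda_not_selected_on_signal_data(self, rng):
        """On BMI-scale data with real signal the 0-1000 search range is
        adequate: the upper boundary is not the optimum."""
        X = rng.normal(size=(80, 4))
        y = 1.0 / (23.0 + 3.0 * X[:, 0] + rng.normal(size=80))
        l1, l2 = tune_elastic_net(X, y, [0.0, 0.1, 10.0, 1000.0],
                                  inner_k=5, inner_repeats=2, seed=1)
        assert l1 < 1000.0 and l2 < 1000.0

    def test_grid_validation(self):
        with pytest.raises(ValidationError):
            tune_elastic_net(np.zeros((10, 2)), np.zeros(10), [])
        with pytest.raises(ValidationError):
            ModelSpec("m", "elastic_net", hyper_grid={"lambda": [0, 2000]})


class TestSVR:
    def test_kernel_properties(self):
        u = np.array([[1.0, 2.0]])
        assert rbf_kernel(u, u, sigma=0.7)[0, 0] == pytest.approx(1.0)
        d = np.linspace(0, 3, 10)
        vals = [rbf_kernel([[0.0]], [[x]], sigma=0.5)[0, 0] for x in d]
        assert np.all(np.diff(vals) < 0)

    def test_matches_dual_qp_oracle_on_toy_problem(self):
        """3-point 1D epsilon-SVR against a quadratic-programming solution of
        the dual (variables a_i = alpha_i - alpha_i*)."""
        x = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 0.4])
        sigma, C, eps = 0.5, 10.0, 0.05

        model = fit_svr_rbf(x, y, sigma=sigma, C=C, epsilon=eps)

        # oracle operates on the same standardized internal problem
        xs = (x - model.x_mean) / model.x_scale
        ys = (y - model.y_mean) / model.y_scale
        K = rbf_kernel(xs, xs, sigma)

        def neg_dual(a):
            return 0.5 * a @ K @ a - ys @ a + eps * np.abs(a).sum()

        cons = [{"type": "eq", "fun": lambda a: a.sum()}]
        res = minimize(
            neg_dual, np.zeros(3), method="SLSQP", constraints=cons,
            bounds=[(-C, C)] * 3, options={"ftol": 1e-14, "maxiter": 500},
        )
        a = res.x
        free = np.flatnonzero((np.abs(a) > 1e-6) & (np.abs(a) < C - 1e-6))
        b = np.mean([ys[i] - (K @ a)[i] - eps * np.sign(a[i]) for i in free])
        pred_std = K @ a + b
        oracle = pred_std * model.y_scale + model.y_mean
        np.testing.assert_allclose(predict(model, x), oracle, atol=1e-4)

    def test_near_interpolation_inside_epsilon_tube(self, rng):
        X = rng.normal(size=(20, 2))
        y = X @ [1.0, -1.0] + rng.normal(size=20) * 0.01
        model = fit_svr_rbf(X, y, sigma=0.5, C=1e4, epsilon=0.01)
        resid_std = np.abs(predict(model, X) - y) / model.y_scale
        assert np.all(resid_std <= 0.01 + 1e-3)

    def test_parameter_validation(self):
        with pytest.raises(ValidationError):
            fit_svr_rbf(np.zeros((5, 1)), np.zeros(5), sigma=0.0, C=1.0)


class TestPredict:
    def test_feature_mismatch_rejected(self, rng):
        model = fit_ols(rng.normal(size=(10, 2)), rng.normal(size=10))
        with pytest.raises(ValidationError):
            predict(model, np.zeros((3, 3)))
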