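import numpy as np
import pytest

from methage.enet import (
    cross_validate,
    fit_elastic_net,
    kkt_max_violation,
    lambda_path,
    standardize,
)


def random_instance(rng, n=None, p=None, noise=0.5):
    n = n or int(rng.integers(10, 41))
    p = p or int(rng.integers(3, 61))
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    k = min(p, 4)
    beta[:k] = rng.normal(scale=2.0, size=k)
    y = X @ beta + rng.normal(scale=noise, size=n)
    return X, y


class TestLambdaPath:
    def test_geometric_spacing(self):
        rng = np.random.default_rng(0)
        X, y = random_instance(rng, n=20, p=5)
        Xs, _, _ = standardize(X)
        yc = y - y.mean()
        grid = lambda_path(Xs, yc, l1_ratio=0.5, n_lambda=3, eps=0.01)
        assert grid[0] == pytest.approx(np.abs(Xs.T @ yc).max() / (20 * 0.5))
        np.testing.assert_allclose(grid / grid[0], [1.0, 0.1, 0.01])

    def test_all_zero_at_lambda_max(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            X, y = random_instance(rng, n=5, p=3)
            Xs, _, _ = standardize(X)
            grid = lambda_path(Xs, y - y.mean(), l1_ratio=0.7)
            fit = fit_elastic_net(Xs, y, grid[0], 0.7, tol=1e-12)
            assert np.all(fit.coefficients == 0.0)
            assert fit.intercept == pytest.approx(y.mean())

    def test_just_below_lambda_max_nonzero(self):
        rng = np.random.default_rng(2)
        X, y = random_instance(rng, n=20, p=5, noise=0.1)
        Xs, _, _ = standardize(X)
        grid = lambda_path(Xs, y - y.mean(), l1_ratio=0.5)
        fit = fit_elastic_net(Xs, y, grid[0] * 0.95, 0.5, tol=1e-12)
        assert (fit.coefficients != 0).any()

    def test_l1_ratio_zero_rejected(self):
        with pytest.raises(ValueError, match="l1_ratio"):
            lambda_path(np.eye(3), np.ones(3), l1_ratio=0.0)

    def test_orthogonal_response_degenerate(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([1.0, 1.0])  # centered y is 0
        with pytest.raises(ValueError, match="degenerate"):
            lambda_path(X, y - y.mean(), l1_ratio=0.5)


class TestFitElasticNet:
    def test_ridge_matches_closed_form(self):
        rng = np.random.default_rng(3)
        X, y = random_instance(rng, n=6, p=2)
        Xs, _, _ = standardize(X)
        lam = 0.4
        fit = fit_elastic_net(Xs, y, lam, l1_ratio=0.0, tol=1e-12, max_iter=100000)
        n = len(y)
        closed = np.linalg.solve(Xs.T @ Xs + n * lam * np.eye(2), Xs.T @ (y - y.mean()))
        np.testing.assert_allclose(fit.coefficients, closed, atol=1e-6)

    def test_lambda_zero_matches_ols(self):
        rng = np.random.default_rng(4)
        X, y = random_instance(rng, n=25, p=4)
        fit = fit_elastic_net(X, y, 0.0, l1_ratio=0.5, tol=1e-13, max_iter=200000)
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), X]), y, rcond=None
        )
        np.testing.assert_allclose(fit.intercept, coef[0], atol=1e-6)
        np.testing.assert_allclose(fit.coefficients, coef[1:], atol=1e-6)

    def test_original_scale_model_reproduces_standardized_predictions(self):
        rng = np.random.default_rng(5)
        X = rng.normal(loc=50, scale=[1.0, 10.0, 0.3], size=(30, 3))
        y = X[:, 0] * 2 - X[:, 1] + rng.normal(size=30)
        fit = fit_elastic_net(X, y, 0.05, 0.5, tol=1e-12)
        Xs = (X - fit.feature_means) / fit.feature_sds
        beta_std = fit.coefficients * fit.feature_sds
        pred_std = y.mean() + Xs @ beta_std
        np.testing.assert_allclose(fit.predict(X), pred_std, atol=1e-8)

    def test_objective_monotone_along_sweeps(self):
        rng = np.random.default_rng(6)
        X, y = random_instance(rng, n=30, p=20)
        fit = fit_elastic_net(X, y, 0.1, 0.5, tol=1e-10, trace=True)
        trace = np.array(fit.objective_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_kkt_satisfied_at_convergence(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            X, y = random_instance(rng)
            lam = float(rng.uniform(0.01, 1.0))
            l1r = float(rng.uniform(0.1, 1.0))
            fit = fit_elastic_net(X, y, lam, l1r, tol=1e-10, max_iter=100000)
            assert kkt_max_violation(X, y, fit) < 1e-7

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(8)
        X, y = random_instance(rng, n=30, p=10)
        perm = rng.permutation(10)
        fit1 = fit_elastic_net(X, y, 0.1, 0.5, tol=1e-12)
        fit2 = fit_elastic_net(X[:, perm], y, 0.1, 0.5, tol=1e-12)
        np.testing.assert_allclose(fit1.coefficients[perm], fit2.coefficients, atol=1e-8)

    def test_constant_column_gets_zero_coefficient(self):
        rng = np.random.default_rng(9)
        X, y = random_instance(rng, n=20, p=3)
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_elastic_net(X, y, 0.1, 0.5)
        assert fit.coefficients[1] == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            fit_elastic_net(np.array([[np.nan], [1.0]]), np.array([1.0, 2.0]), 0.1)

    def test_max_iter_warning_and_flag(self):
        rng = np.random.default_rng(10)
        X, y = random_instance(rng, n=40, p=30)
        with pytest.warns(UserWarning, match="max_iter"):
            fit = fit_elastic_net(X, y, 1e-8, 0.5, tol=1e-14, max_iter=2)
        assert not fit.converged

    def test_warm_start_converges_to_same_solution(self):
        rng = np.random.default_rng(11)
        X, y = random_instance(rng, n=30, p=15)
        cold = fit_elastic_net(X, y, 0.2, 0.5, tol=1e-12)
        warm = fit_elastic_net(
            X, y, 0.2, 0.5, tol=1e-12, warm_start=rng.normal(size=15)
        )
        np.testing.assert_allclose(cold.coefficients, warm.coefficients, atol=1e-8)

    def test_agreement_with_sklearn_on_random_instances(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(12)
        for _ in range(50):
            X, y = random_instance(rng)
            Xs, _, _ = standardize(X)
            lam = float(rng.uniform(0.01, 0.5))
            l1r = float(rng.choice([0.0, 0.2, 0.5, 0.8, 1.0]))
            ours = fit_elastic_net(Xs, y, lam, l1r, tol=1e-11, max_iter=200000)
            ref = sklearn.ElasticNet(
                alpha=lam, l1_ratio=l1r, tol=1e-12, max_iter=1000000
            ).fit(Xs, y)
            scale = max(1e-12, np.abs(ref.coef_).max())
            assert np.abs(ours.coefficients - ref.coef_).max() / scale < 1e-4
            assert ours.intercept == pytest.approx(ref.intercept_, abs=1e-6)


class TestSolverPaths:
    def test_compiled_kernel_matches_pure_python(self):
        """trace=True forces the pure-Python sweep; results must match the
        compiled kernel used in production runs."""
        rng = np.random.default_rng(99)
        X, y = random_instance(rng, n=30, p=25)
        fast = fit_elastic_net(X, y, 0.1, 0.5, tol=1e-10)
        slow = fit_elastic_net(X, y, 0.1, 0.5, tol=1e-10, trace=True)
        np.testing.assert_allclose(fast.coefficients, slow.coefficients, atol=1e-9)
        assert fast.intercept == pytest.approx(slow.intercept, abs=1e-9)


class TestCrossValidate:
    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(13)
        X, y = random_instance(rng, n=40, p=10)
        strata = ["a", "b"] * 20
        cv1 = cross_validate(X, y, strata, n_folds=4, l1_ratio=0.5, seed=5)
        cv2 = cross_validate(X, y, strata, n_folds=4, l1_ratio=0.5, seed=5)
        assert np.array_equal(cv1.fold_assignments, cv2.fold_assignments)
        assert cv1.best_lambda == cv2.best_lambda

    def test_fold_sizes_balanced_within_stratum(self):
        rng = np.random.default_rng(14)
        X, y = random_instance(rng, n=37, p=5)
        strata = np.array(["a"] * 20 + ["b"] * 17)
        cv = cross_validate(X, y, strata, n_folds=5, l1_ratio=0.5, seed=0)
        for label in ("a", "b"):
            sizes = np.bincount(cv.fold_assignments[strata == label], minlength=5)
            assert sizes.max() - sizes.min() <= 1

    def test_best_beats_lambda_max_on_signal(self):
        rng = np.random.default_rng(15)
        n, p = 60, 20
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:5] = [3, -2, 1.5, 2, -1]
        y = X @ beta + rng.normal(scale=0.3, size=n)
        cv = cross_validate(X, y, ["s"] * n, n_folds=5, l1_ratio=0.5, seed=1)
        assert cv.mean_mse[cv.best_index] <= cv.mean_mse[0]
        assert cv.best_lambda < cv.lambda_grid[0]

    def test_duplicate_features_share_weight_in_ridge_limit(self):
        rng = np.random.default_rng(16)
        n = 40
        x = rng.normal(size=n)
        y = 2.0 * x + rng.normal(scale=0.05, size=n)
        X1 = x[:, None]
        X2 = np.column_stack([x, x])  # exact duplicate feature
        lam = 0.5
        solo = fit_elastic_net(X1, y, lam, l1_ratio=0.0, tol=1e-12)
        dup = fit_elastic_net(X2, y, lam, l1_ratio=0.0, tol=1e-12)
        # ridge symmetry: the duplicates split the weight evenly
        assert dup.coefficients[0] == pytest.approx(dup.coefficients[1], rel=1e-6)
        # and jointly carry at least the single-feature (more-shrunk) weight
        assert dup.coefficients.sum() >= solo.coefficients[0]

    def test_small_stratum_distributed_with_warning(self):
        rng = np.random.default_rng(17)
        X, y = random_instance(rng, n=23, p=5)
        strata = ["big"] * 20 + ["tiny"] * 3
        with pytest.warns(UserWarning, match="tiny"):
            cv = cross_validate(X, y, strata, n_folds=5, l1_ratio=0.5, seed=0)
        tiny_folds = cv.fold_assignments[20:]
        assert len(set(tiny_folds.tolist())) == 3  # one per fold

    def test_grid_strictly_decreasing_enforced(self):
        rng = np.random.default_rng(18)
        X, y = random_instance(rng, n=20, p=4)
        with pytest.raises(ValueError, match="decreasing"):
            cross_validate(
                X, y, ["s"] * 20, n_folds=4, l1_ratio=0.5,
                lambda_grid=np.array([0.1, 0.2]), seed=0,
            )

    def test_one_se_rule_picks_larger_lambda(self):
        rng = np.random.default_rng(19)
        X, y = random_instance(rng, n=50, p=15)
        cv = cross_validate(X, y, ["s"] * 50, n_folds=5, l1_ratio=0.5, seed=3)
        assert cv.best_lambda_1se() >= cv.best_lambda
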