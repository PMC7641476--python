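"""The in-memory elastic-net solver: closed forms, oracles, invariants."""

import numpy as np
import pytest

from basilnet import (
    BINOMIAL,
    GAUSSIAN,
    PenaltySpec,
    covariate_only_fit,
    fit_path_on_strong_set,
    relaxed_refit,
    soft_threshold,
)
from basilnet.errors import CollinearityError
from basilnet.families import loss


class TestSoftThreshold:
    @pytest.mark.parametrize("z,gamma,expected", [
        (3.0, 1.0, 2.0),
        (-0.5, 1.0, 0.0),
        (-3.0, 1.0, -2.0),
        (0.0, 0.0, 0.0),
    ])
    def test_scalar_values(self, z, gamma, expected):
        assert soft_threshold(z, gamma) == expected

    def test_vectorized(self):
        np.testing.assert_allclose(
            soft_threshold(np.array([3.0, -0.5, -3.0]), 1.0),
            [2.0, 0.0, -2.0],
        )


def ista_reference(X, y, lam, alpha=1.0, n_iter=200_000, tol=1e-14):
    """Proximal-gradient reference for the gaussian elastic net (no intercept)."""
    n, p = X.shape
    L = np.linalg.norm(X, 2) ** 2 / n + lam * (1 - alpha)
    beta = np.zeros(p)
    for _ in range(n_iter):
        grad = -X.T @ (y - X @ beta) / n + lam * (1 - alpha) * beta
        new = soft_threshold(beta - grad / L, lam * alpha / L)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


class TestGaussianPath:
    def test_single_variable_closed_form(self):
        rng = np.random.default_rng(0)
        for alpha in (1.0, 0.5):
            x = rng.normal(size=(30, 1))
            y = rng.normal(size=30)
            lam = 0.3 * abs(x[:, 0] @ y) / 30 / alpha
            fit = fit_path_on_strong_set(
                x, None, y, GAUSSIAN,
                PenaltySpec(lambda_values=np.array([lam]), alpha_mix=alpha),
                fit_intercept=False,
            )
            n = 30
            expected = soft_threshold(x[:, 0] @ y / n, lam * alpha) / (
                x[:, 0] @ x[:, 0] / n + lam * (1 - alpha)
            )
            assert fit.coefficients[0, 0] == pytest.approx(expected, abs=1e-10)

    def test_lambda_max_all_zero_intercept_is_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 8))
        y = rng.normal(size=50)
        r0 = y - y.mean()
        lam_max = np.max(np.abs(X.T @ r0)) / 50
        fit = fit_path_on_strong_set(
            X, None, y, GAUSSIAN, PenaltySpec(lambda_values=np.array([lam_max * 1.001]))
        )
        assert np.all(fit.coefficients == 0.0)
        assert fit.intercept[0] == pytest.approx(y.mean())

    def test_matches_proximal_gradient_reference(self):
        rng = np.random.default_rng(2)
        n, p = 60, 12
        X = rng.normal(size=(n, p))
        y = X[:, 0] * 0.5 - X[:, 3] * 0.8 + rng.normal(size=n)
        lam = 0.1
        fit = fit_path_on_strong_set(
            X, None, y, GAUSSIAN, PenaltySpec(lambda_values=np.array([lam])),
            fit_intercept=False,
        )
        ref = ista_reference(X, y, lam)
        beta = fit.coefficients[:, 0]

        def objective(b):
            r = y - X @ b
            return 0.5 * r @ r / n + lam * np.abs(b).sum()

        assert objective(beta) <= objective(ref) + 1e-8
        # KKT at the returned solution
        g = X.T @ (y - X @ beta) / n
        act = beta != 0
        assert np.all(np.abs(g[~act]) <= lam + 1e-8)
        assert np.all(np.abs(g[act] - lam * np.sign(beta[act])) <= 1e-8)

    def test_warm_start_equivalence(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 20))
        y = X[:, :3] @ np.array([1.0, -0.5, 0.7]) + rng.normal(size=80)
        lams = np.array([0.3, 0.1])
        warm = fit_path_on_strong_set(X, None, y, GAUSSIAN,
                                      PenaltySpec(lambda_values=lams))
        for i, lam in enumerate(lams):
            cold = fit_path_on_strong_set(
                X, None, y, GAUSSIAN, PenaltySpec(lambda_values=np.array([lam]))
            )
            np.testing.assert_allclose(
                warm.coefficients[:, i], cold.coefficients[:, 0], atol=1e-8
            )

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 15))
        y = rng.normal(size=60)
        fit = fit_path_on_strong_set(
            X, None, y, GAUSSIAN, PenaltySpec(lambda_values=np.array([0.2, 0.05]))
        )
        for lam_traces in fit.objective_traces:
            for arr in lam_traces:
                assert np.all(np.diff(arr) <= 1e-12)

    def test_unpenalized_covariates_block_stationarity(self):
        rng = np.random.default_rng(5)
        n = 70
        X = rng.normal(size=(n, 10))
        Z = rng.normal(size=(n, 2))
        y = Z @ np.array([1.0, -2.0]) + X[:, 0] + rng.normal(size=n)
        fit = fit_path_on_strong_set(
            X, Z, y, GAUSSIAN, PenaltySpec(lambda_values=np.array([0.15]))
        )
        # given the penalized block, covariates+intercept solve their own OLS
        resid_pen = y - X @ fit.coefficients[:, 0]
        D0 = np.column_stack([np.ones(n), Z])
        theta, *_ = np.linalg.lstsq(D0, resid_pen, rcond=None)
        assert fit.intercept[0] == pytest.approx(theta[0], abs=1e-8)
        np.testing.assert_allclose(fit.covariate_coefficients[:, 0], theta[1:],
                                   atol=1e-8)


class TestBinomialPath:
    def test_kkt_at_solution(self):
        rng = np.random.default_rng(6)
        n, p = 120, 25
        X = rng.normal(size=(n, p))
        eta = X[:, 0] - 0.8 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        r0 = y - y.mean()
        lam = 0.4 * np.max(np.abs(X.T @ r0)) / n
        fit = fit_path_on_strong_set(
            X, None, y, BINOMIAL, PenaltySpec(lambda_values=np.array([lam]))
        )
        p_hat = 1 / (1 + np.exp(-fit.linear_predictor[:, 0]))
        g = X.T @ (y - p_hat) / n
        beta = fit.coefficients[:, 0]
        act = beta != 0
        assert act.sum() > 0
        assert np.all(np.abs(g[~act]) <= lam * (1 + 1e-6))
        np.testing.assert_allclose(g[act], lam * np.sign(beta[act]), atol=1e-7)

    def test_sklearn_cross_check(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(7)
        n, p = 150, 10
        X = rng.normal(size=(n, p))
        y = (rng.random(n) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
        lam = 0.02
        fit = fit_path_on_strong_set(
            X, None, y, BINOMIAL, PenaltySpec(lambda_values=np.array([lam]))
        )
        clf = sklearn.LogisticRegression(
            penalty="l1", C=1.0 / (n * lam), solver="saga", tol=1e-10,
            max_iter=50_000,
        )
        clf.fit(X, y)
        np.testing.assert_allclose(fit.coefficients[:, 0], clf.coef_[0], atol=2e-4)


class TestCovariateOnlyFit:
    def test_gaussian_centering(self):
        out = covariate_only_fit(None, np.array([1.0, 2.0, 3.0]), GAUSSIAN)
        np.testing.assert_allclose(out.residual, [-1.0, 0.0, 1.0])
        assert out.intercept == pytest.approx(2.0)

    def test_gaussian_orthogonality(self):
        rng = np.random.default_rng(8)
        Z = (rng.random((40, 1)) < 0.5).astype(float)
        y = rng.normal(size=40)
        out = covariate_only_fit(Z, y, GAUSSIAN)
        assert abs(out.residual @ Z[:, 0]) < 1e-10
        assert abs(out.residual.sum()) < 1e-10

    def test_binomial_base_rate(self):
        y = np.array([1.0, 0.0, 0.0, 0.0] * 5)
        out = covariate_only_fit(None, y, BINOMIAL)
        np.testing.assert_allclose(out.residual, y - 0.25, atol=1e-8)

    def test_collinearity_error_names_columns(self):
        Z = np.ones((20, 2))
        Z[:, 1] = 2.0  # both collinear with the intercept
        with pytest.raises(CollinearityError):
            covariate_only_fit(Z, np.random.default_rng(9).normal(size=20), GAUSSIAN)


class TestRelaxedRefit:
    def test_empty_active_set_reduces_to_covariate_fit(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=30)
        cov, act = relaxed_refit(np.empty((30, 0)), None, y, GAUSSIAN)
        assert act.size == 0
        assert cov[0] == pytest.approx(y.mean())

    def test_orthonormal_columns(self):
        rng = np.random.default_rng(11)
        raw = rng.normal(size=(50, 4))
        raw -= raw.mean(axis=0)  # orthogonal to the intercept
        Q, _ = np.linalg.qr(raw)
        y = rng.normal(size=50)
        _, act = relaxed_refit(Q, None, y, GAUSSIAN)
        np.testing.assert_allclose(act, Q.T @ y, atol=1e-10)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(12)
        n = 60
        X_A = rng.normal(size=(n, 5))
        Z = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        cov, act = relaxed_refit(X_A, Z, y, GAUSSIAN)
        D = np.column_stack([np.ones(n), Z, X_A])
        theta = np.linalg.solve(D.T @ D, D.T @ y)
        np.testing.assert_allclose(np.concatenate([cov, act]), theta, atol=1e-8)

    def test_never_increases_in_sample_loss(self):
        rng = np.random.default_rng(13)
        n, p = 80, 30
        X = rng.normal(size=(n, p))
        y = X[:, 0] + rng.normal(size=n)
        lam = 0.15
        fit = fit_path_on_strong_set(
            X, None, y, GAUSSIAN, PenaltySpec(lambda_values=np.array([lam]))
        )
        beta = fit.coefficients[:, 0]
        act = np.nonzero(beta)[0]
        cov, act_coef = relaxed_refit(X[:, act], None, y, GAUSSIAN)
        eta_relax = cov[0] + X[:, act] @ act_coef
        assert loss(GAUSSIAN, y, eta_relax) <= loss(GAUSSIAN, y, fit.linear_predictor[:, 0]) + 1e-12

    def test_rank_deficient_warns(self):
        rng = np.random.default_rng(14)
        X_A = rng.normal(size=(20, 3))
        X_A[:, 2] = X_A[:, 0]  # duplicate column
        with pytest.warns(RuntimeWarning):
            relaxed_refit(X_A, None, rng.normal(size=20), GAUSSIAN)


class TestPenaltySpec:
    def test_rejects_increasing_lambdas(self):
        with pytest.raises(ValueError):
            PenaltySpec(lambda_values=np.array([0.1, 0.2]))

    def test_rejects_all_zero_penalty_factors(self):
        with pytest.raises(ValueError):
            PenaltySpec(lambda_values=np.array([0.1]), penalty_factor=np.zeros(3))

    def test_rejects_alpha_zero(self):
        with pytest.raises(ValueError):
            PenaltySpec(lambda_values=np.array([0.1]), alpha_mix=0.0)
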