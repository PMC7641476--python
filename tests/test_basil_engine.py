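"""The outer loop: lambda grid, screening, KKT certification, full runs."""

import numpy as np
import pytest

from basilnet import (
    BasilConfig,
    GAUSSIAN,
    PenaltySpec,
    basil_run,
    fit_path_on_strong_set,
    initial_batch_heuristic,
    kkt_check,
    lambda_sequence,
    load_block,
    open_store,
    predict,
    screen,
    simulate_dataset,
    SimulationSpec,
    split_indices,
)
from basilnet.basil_engine import _batch_from_stats
from basilnet.errors import AlignmentError, ConfigError


@pytest.fixture(scope="module")
def gaussian_dataset(tmp_path_factory):
    spec = SimulationSpec(
        n_samples=300, n_variants=400, n_causal=10, heritability=0.6,
        missing_rate=0.02, seed=21,
    )
    data = simulate_dataset(spec, tmp_path_factory.mktemp("eng") / "g")
    store = open_store(data["bed"], data["bim"], data["fam"])
    return store, data


class TestLambdaSequence:
    def test_log_spacing(self):
        np.testing.assert_allclose(lambda_sequence(1.0, 3, 0.01), [1.0, 0.1, 0.01])

    def test_inner_product_arithmetic(self):
        x = np.array([1.0, -1.0])
        r0 = np.array([1.0, -1.0])
        lam1 = np.abs(x @ r0) / 2
        assert lambda_sequence(lam1, 5, 0.1)[0] == pytest.approx(1.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            lambda_sequence(0.0, 10, 0.01)

    def test_strictly_decreasing(self):
        lams = lambda_sequence(2.5, 100, 0.01)
        assert np.all(np.diff(lams) < 0)


class TestScreen:
    def test_top_m_with_active_kept(self):
        c = np.array([0.9, 0.1, 0.5, 0.7])
        S = screen(c, {2}, 2)
        assert set(S) == {0, 2, 3}

    def test_m_at_least_p_saturates(self):
        c = np.random.default_rng(0).random(7)
        assert set(screen(c, set(), 100)) == set(range(7))

    def test_full_active_set(self):
        c = np.random.default_rng(1).random(5)
        assert set(screen(c, set(range(5)), 2)) == set(range(5))

    def test_tie_break_by_index(self):
        c = np.array([0.5, 0.5, 0.5, 0.5])
        assert list(screen(c, set(), 2)) == [0, 1]

    def test_rejects_nonpositive_m(self):
        with pytest.raises(ConfigError):
            screen(np.ones(3), set(), 0)


class TestKktCheck:
    def test_zero_solution_at_lambda_max_passes(self, gaussian_dataset):
        store, data = gaussian_dataset
        y = data["response"]
        X = load_block(store, np.arange(store.n_variants)).matrix
        n = store.n_samples
        lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
        S = np.array([0])
        fit = fit_path_on_strong_set(
            X[:, S], None, y, GAUSSIAN,
            PenaltySpec(lambda_values=np.array([lam_max * 1.0001])),
        )
        lam_bar, viol = kkt_check(
            fit, store, S, 1.0, 1e-6,
            lambdas=np.array([lam_max * 1.0001]), response=y, family=GAUSSIAN,
            universe=np.arange(store.n_variants),
            impute_values=X.mean(axis=0),
        )
        assert lam_bar == 0 and not viol

    def test_full_solution_passes_every_lambda(self, gaussian_dataset):
        store, data = gaussian_dataset
        y = data["response"]
        universe = np.arange(store.n_variants)
        X = load_block(store, universe).matrix
        n = store.n_samples
        lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
        lams = lambda_sequence(lam_max, 8, 0.05)
        S = universe  # strong set = everything -> oracle full-data solution
        fit = fit_path_on_strong_set(X, None, y, GAUSSIAN,
                                     PenaltySpec(lambda_values=lams))
        # restrict the reported strong set to each lambda's support union:
        # certify against variants outside the union of active sets
        support = np.nonzero(np.any(fit.coefficients != 0, axis=1))[0]
        imput = np.array([X[:, j].mean() for j in universe])
        lam_bar, viol = kkt_check(
            fit, store, support, 1.0, 1e-6, lambdas=lams, response=y,
            family=GAUSSIAN, universe=universe,
            impute_values=imput,
        )
        assert lam_bar == len(lams) - 1
        assert not viol

    def test_planted_violation_reported(self, gaussian_dataset):
        store, data = gaussian_dataset
        y = data["response"]
        universe = np.arange(store.n_variants)
        X = load_block(store, universe).matrix
        n = store.n_samples
        stats = np.abs(X.T @ (y - y.mean())) / n
        top = int(np.argmax(stats))
        lam_small = 0.5 * stats[top]  # top variant violates at this lambda
        S = np.array([j for j in range(5) if j != top])
        fit = fit_path_on_strong_set(
            X[:, S], None, y, GAUSSIAN,
            PenaltySpec(lambda_values=np.array([lam_small])),
        )
        lam_bar, viol = kkt_check(
            fit, store, S, 1.0, 1e-6,
            lambdas=np.array([lam_small]), response=y, family=GAUSSIAN,
            universe=universe, impute_values=np.array([X[:, j].mean() for j in universe]),
        )
        assert lam_bar is None
        assert top in viol[0]


class TestBasilRun:
    def test_matches_full_matrix_oracle(self, gaussian_dataset):
        store, data = gaussian_dataset
        cfg = BasilConfig(batch_m=40, delta_m=20, n_lambda=40, early_stopping=False)
        sol = basil_run(store, data["response"], None, cfg)
        assert sol.lambda_values.size == 40
        X = load_block(store, sol.qc_indices,
                       sol.impute_values[sol.qc_indices]).matrix
        full = fit_path_on_strong_set(
            X, None, data["response"], GAUSSIAN,
            PenaltySpec(lambda_values=sol.lambda_values),
        )
        B = sol.coefficients[sol.qc_indices, :].toarray()
        assert np.max(np.abs(B - full.coefficients)) < 1e-4

    def test_batch_size_invariance(self, gaussian_dataset):
        store, data = gaussian_dataset
        sols = [
            basil_run(store, data["response"], None,
                      BasilConfig(batch_m=M, delta_m=10, n_lambda=25,
                                  early_stopping=False))
            for M in (5, 400)
        ]
        assert sols[0].lambda_values.size == sols[1].lambda_values.size
        dev = np.max(np.abs((sols[0].coefficients - sols[1].coefficients).toarray()))
        assert dev < 1e-6

    def test_degenerate_single_batch(self, gaussian_dataset):
        store, data = gaussian_dataset
        cfg = BasilConfig(batch_m=400, lambdas_per_iteration=20, n_lambda=20,
                          early_stopping=False)
        sol = basil_run(store, data["response"], None, cfg)
        assert sol.n_iterations <= 2
        X = load_block(store, sol.qc_indices,
                       sol.impute_values[sol.qc_indices]).matrix
        plain = fit_path_on_strong_set(
            X, None, data["response"], GAUSSIAN,
            PenaltySpec(lambda_values=sol.lambda_values),
        )
        B = sol.coefficients[sol.qc_indices, :].toarray()
        assert np.max(np.abs(B - plain.coefficients)) < 1e-6

    def test_pass_economy(self, gaussian_dataset):
        store, data = gaussian_dataset
        sol = basil_run(store, data["response"], None,
                        BasilConfig(batch_m=30, delta_m=15, n_lambda=30,
                                    early_stopping=False))
        assert sol.n_full_scans == sol.n_iterations

    def test_adversarial_m1_terminates(self, tmp_path):
        spec = SimulationSpec(n_samples=120, n_variants=50, n_causal=5,
                              heritability=0.7, missing_rate=0.0, seed=33)
        data = simulate_dataset(spec, tmp_path / "adv")
        store = open_store(data["bed"], data["bim"], data["fam"])
        cfg = BasilConfig(batch_m=1, delta_m=1, n_lambda=20, early_stopping=False)
        sol = basil_run(store, data["response"], None, cfg)
        assert sol.lambda_values.size == 20
        # exact certification: full-matrix comparison
        X = load_block(store, sol.qc_indices,
                       sol.impute_values[sol.qc_indices]).matrix
        full = fit_path_on_strong_set(
            X, None, data["response"], GAUSSIAN,
            PenaltySpec(lambda_values=sol.lambda_values),
        )
        B = sol.coefficients[sol.qc_indices, :].toarray()
        assert np.max(np.abs(B - full.coefficients)) < 1e-4

    def test_validation_early_stop_and_covariates(self, tmp_path):
        spec = SimulationSpec(n_samples=400, n_variants=300, n_causal=8,
                              heritability=0.5, n_covariates=2, seed=44)
        data = simulate_dataset(spec, tmp_path / "val")
        store = open_store(data["bed"], data["bim"], data["fam"])
        tr, va, te = split_indices(400, seed=44)
        cfg = BasilConfig(batch_m=50, delta_m=25, n_lambda=60)
        sol = basil_run(store, data["response"], data["covariates"], cfg, tr, va)
        assert sol.best_index is not None
        assert sol.validation_metric is not None
        assert sol.covariate_coefficients.shape[0] == 2
        # early stopping should have cut the path short of 60
        assert sol.lambda_values.size < 60

    def test_alignment_errors(self, gaussian_dataset):
        store, data = gaussian_dataset
        with pytest.raises(AlignmentError):
            basil_run(store, data["response"][:-3], None, BasilConfig())
        with pytest.raises(AlignmentError):
            basil_run(store, data["response"], None, BasilConfig(),
                      np.arange(100), np.arange(50, 150))


class TestInitialBatchHeuristic:
    def test_matches_brute_force(self, gaussian_dataset):
        store, data = gaussian_dataset
        y = data["response"]
        r0 = y - y.mean()
        X = load_block(store, np.arange(store.n_variants)).matrix
        stats = np.abs(X.T @ r0) / store.n_samples
        lams = lambda_sequence(stats.max(), 50, 0.01)
        got = initial_batch_heuristic(store, r0, lams, target_index=10,
                                      min_batch=1)
        expected = max(int(np.sum(stats > 2 * lams[9] - lams[0])), 1)
        assert got == expected

    def test_floor_applied_at_target_one(self):
        stats = np.random.default_rng(2).random(500)
        lams = lambda_sequence(stats.max(), 20, 0.01)
        assert _batch_from_stats(stats, lams, 1, 100) == 100

    def test_monotone_in_target_index(self, gaussian_dataset):
        store, data = gaussian_dataset
        y = data["response"]
        r0 = y - y.mean()
        X = load_block(store, np.arange(store.n_variants)).matrix
        stats = np.abs(X.T @ r0) / store.n_samples
        lams = lambda_sequence(stats.max(), 50, 0.01)
        counts = [_batch_from_stats(stats, lams, t, 1) for t in (2, 5, 10, 20)]
        assert counts == sorted(counts)


class TestPredict:
    def test_constant_prediction_with_zero_coefficients(self, gaussian_dataset):
        store, data = gaussian_dataset
        cfg = BasilConfig(batch_m=40, n_lambda=5, lambda_min_ratio=0.9,
                          early_stopping=False)
        sol = basil_run(store, data["response"], None, cfg)
        pred = predict(sol, store, lam=0)
        if sol.coefficients[:, 0].nnz == 0:
            np.testing.assert_allclose(pred, sol.intercepts[0])

    def test_matches_dense_oracle(self, gaussian_dataset):
        store, data = gaussian_dataset
        cfg = BasilConfig(batch_m=60, n_lambda=20, early_stopping=False)
        sol = basil_run(store, data["response"], None, cfg)
        ci = sol.lambda_values.size - 1
        pred = predict(sol, store, lam=ci)
        X = load_block(store, np.arange(store.n_variants),
                       sol.impute_values).matrix
        expected = sol.intercepts[ci] + X @ sol.coefficients[:, ci].toarray()[:, 0]
        np.testing.assert_allclose(pred, expected, rtol=1e-10)

    def test_universe_mismatch(self, gaussian_dataset, tmp_path):
        store, data = gaussian_dataset
        sol = basil_run(store, data["response"], None,
                        BasilConfig(batch_m=40, n_lambda=5, early_stopping=False))
        other = simulate_dataset(
            SimulationSpec(n_samples=10, n_variants=7, n_causal=2, seed=1),
            tmp_path / "o",
        )
        other_store = open_store(other["bed"], other["bim"], other["fam"])
        with pytest.raises(AlignmentError):
            predict(sol, other_store, lam=0)
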