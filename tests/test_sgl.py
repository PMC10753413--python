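import numpy as np
import pytest

import oracles
from phenocell import errors
from phenocell.containers import PhenotypeVector
from phenocell.sgl import (
    cox_loss,
    cross_validate,
    fit_sgl,
    kkt_check,
    lambda_max,
    logistic_loss,
    sgl_objective,
)


def binary_pheno(y):
    y = np.asarray(y, dtype=float)
    return PhenotypeVector([f"s{i}" for i in range(len(y))], "binary", y=y)


def survival_pheno(time, status):
    return PhenotypeVector([f"s{i}" for i in range(len(time))], "survival",
                           time=np.asarray(time, float),
                           status=np.asarray(status, float))


def seeded_instance(seed=0, n=10, N=20, n_groups=4):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, N))
    y = np.zeros(n)
    y[: n // 2] = 1.0
    rng.shuffle(y)
    groups = np.repeat(np.arange(n_groups), N // n_groups)
    return X, binary_pheno(y), groups


class TestLogisticLoss:
    def test_null_model_is_n_ln2(self):
        X = np.zeros((4, 3))
        assert logistic_loss(X, binary_pheno([1, 0, 1, 0]),
                             np.zeros(3)) == pytest.approx(4 * np.log(2),
                                                           abs=1e-12)

    def test_saturation_limit(self):
        X = np.array([[1.0]])
        loss = logistic_loss(X, binary_pheno([1]), np.array([40.0]))
        assert loss < 1e-12

    def test_matches_direct_formula_on_random_instance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 8))
        beta = rng.normal(size=8)
        b0 = 0.3
        y = np.array([1.0, 0, 0, 1, 1])
        eta = X @ beta + b0
        direct = sum(np.log(1 + np.exp(e)) - yi * e for e, yi in zip(eta, y))
        assert logistic_loss(X, binary_pheno(y), beta, b0) == pytest.approx(
            direct, rel=1e-12)


class TestCoxLoss:
    def test_two_event_closed_form(self):
        X = np.zeros((2, 3))
        loss = cox_loss(X, survival_pheno([2.0, 1.0], [1, 1]), np.zeros(3))
        assert loss == pytest.approx(np.log(2), abs=1e-12)

    def test_all_censored_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(errors.ValidationError):
            cox_loss(X, survival_pheno([1, 2, 3], [0, 0, 0]), np.zeros(2))

    def test_matches_breslow_oracle_with_tie(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 4))
        beta = rng.normal(size=4) * 0.5
        time = np.array([3.0, 1.0, 4.0, 3.0, 2.0, 5.0])  # tie at t=3
        status = np.array([1, 1, 0, 1, 0, 1.0])
        assert cox_loss(X, survival_pheno(time, status), beta) == pytest.approx(
            oracles.breslow_negative_log_partial_likelihood(X, beta, time,
                                                            status),
            rel=1e-12)

    def test_no_overflow_at_large_eta(self):
        X = np.eye(3) * 500.0
        loss = cox_loss(X, survival_pheno([1, 2, 3], [1, 1, 1]), np.ones(3))
        assert np.isfinite(loss)


class TestObjective:
    def test_zero_beta_is_scaled_loss(self):
        assert sgl_objective(8.0, np.zeros(4), 4, 0.3, 0.5,
                             [2, 2]) == pytest.approx(2.0)

    def test_alpha_one_is_pure_lasso(self):
        beta = np.array([1.0, -2.0, 0.5])
        val = sgl_objective(0.0, beta, 5, 0.2, 1.0, [3])
        assert val == pytest.approx(0.2 * 3.5)

    def test_alpha_zero_group_norm(self):
        beta = np.ones(4)
        val = sgl_objective(0.0, beta, 5, 0.25, 0.0, [4])
        assert val == pytest.approx(0.25 * 2.0 * 2.0)  # sqrt(4)*||b||=2*2

    def test_parameter_validation(self):
        with pytest.raises(errors.ValidationError):
            sgl_objective(1.0, np.zeros(2), 2, 0.1, 1.5, [2])
        with pytest.raises(errors.ValidationError):
            sgl_objective(1.0, np.zeros(2), 2, -0.1, 0.5, [2])


class TestLambdaMax:
    @pytest.mark.parametrize("alpha", [0.0, 0.3, 0.7, 1.0])
    def test_zero_above_and_active_below(self, alpha):
        X, pheno, groups = seeded_instance(seed=1)
        lmax = lambda_max(X, pheno, groups, alpha)
        hi = fit_sgl(X, pheno, groups, alpha, lam=lmax * 1.01, tol=1e-7)
        assert np.all(hi.coef == 0.0)
        lo = fit_sgl(X, pheno, groups, alpha, lam=lmax * 0.90, tol=1e-7)
        assert np.count_nonzero(lo.coef) > 0

    def test_pure_lasso_closed_form(self):
        X, pheno, groups = seeded_instance(seed=2)
        pbar = pheno.y.mean()
        g = X.T @ (pbar - pheno.y) / len(pheno.y)
        assert lambda_max(X, pheno, groups, 1.0) == pytest.approx(
            np.abs(g).max(), rel=1e-12)

    def test_constant_design_rejected(self):
        X = np.ones((6, 4))
        with pytest.raises(errors.ValidationError):
            lambda_max(X, binary_pheno([1, 0, 1, 0, 1, 0]),
                       np.zeros(4, dtype=int), 0.5)


class TestFitSGL:
    def test_alpha_one_matches_coordinate_descent_oracle(self):
        X, pheno, groups = seeded_instance(seed=3)
        lam = 0.5 * lambda_max(X, pheno, groups, 1.0)
        fit = fit_sgl(X, pheno, groups, 1.0, lam=lam, tol=1e-8)
        beta_o, b0_o = oracles.logistic_lasso_cd(X, pheno.y, lam)
        np.testing.assert_allclose(fit.coef, beta_o, atol=1e-6)
        assert fit.intercept == pytest.approx(b0_o, abs=1e-5)

    def test_alpha_zero_zero_groups_satisfy_subgradient_bound(self):
        X, pheno, groups = seeded_instance(seed=3)
        lam = 0.5 * lambda_max(X, pheno, groups, 0.0)
        fit = fit_sgl(X, pheno, groups, 0.0, lam=lam, tol=1e-8)
        from scipy.special import expit

        eta = X @ fit.coef + fit.intercept
        grad = X.T @ (expit(eta) - pheno.y) / len(pheno.y)
        saw_zero_group = False
        for g in range(groups.max() + 1):
            idx = groups == g
            if np.all(fit.coef[idx] == 0):
                saw_zero_group = True
                assert np.linalg.norm(grad[idx]) <= lam * np.sqrt(
                    idx.sum()) + 1e-8
        assert saw_zero_group

    @pytest.mark.parametrize("mode", ["binary", "survival"])
    def test_objective_monotone_across_sweeps(self, mode):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(25, 30))
        groups = np.repeat(np.arange(5), 6)
        if mode == "binary":
            pheno = binary_pheno(rng.integers(0, 2, 25))
        else:
            pheno = survival_pheno(rng.exponential(1, 25) + 0.1,
                                   rng.integers(0, 2, 25) | 1)
        lmax = lambda_max(X, pheno, groups, 0.4)
        for fit in fit_sgl(X, pheno, groups, 0.4,
                           lam=lmax * np.array([0.5, 0.2, 0.05]), tol=1e-6):
            trace = fit.objective_trace
            assert np.all(np.diff(trace) <= 1e-9)

    def test_warm_path_continuity_refines(self):
        X, pheno, groups = seeded_instance(seed=5, n=20, N=16)
        lmax = lambda_max(X, pheno, groups, 0.5)

        def max_step(n_points):
            path = np.logspace(np.log10(lmax), np.log10(0.01 * lmax),
                               n_points)
            fits = fit_sgl(X, pheno, groups, 0.5, lam=path, tol=1e-6)
            betas = np.array([f.coef for f in fits])
            return np.max(np.abs(np.diff(betas, axis=0)))

        assert max_step(100) < max_step(20)

    def test_group_permutation_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 12))
        groups = np.repeat(np.arange(3), 4)
        pheno = binary_pheno(rng.integers(0, 2, 30))
        lam = 0.3 * lambda_max(X, pheno, groups, 0.5)
        fit = fit_sgl(X, pheno, groups, 0.5, lam=lam, tol=1e-10)
        # move group 2 first (columns stay with their groups)
        perm = np.concatenate([np.arange(8, 12), np.arange(0, 8)])
        fit_p = fit_sgl(X[:, perm], pheno, np.repeat([0, 1, 2], 4), 0.5,
                        lam=lam, tol=1e-10)
        np.testing.assert_allclose(fit_p.coef, fit.coef[perm], atol=1e-9)
        assert fit_p.objective == pytest.approx(fit.objective, abs=1e-9)

    def test_decreasing_path_required(self):
        X, pheno, groups = seeded_instance(seed=7)
        with pytest.raises(errors.ValidationError):
            fit_sgl(X, pheno, groups, 0.5, lam=np.array([0.1, 0.2]))


class TestKKT:
    def test_converged_fit_within_tolerance(self):
        X, pheno, groups = seeded_instance(seed=3)
        tol = 1e-6
        lam = 0.3 * lambda_max(X, pheno, groups, 0.5)
        fit = fit_sgl(X, pheno, groups, 0.5, lam=lam, tol=tol)
        _, max_res = kkt_check(fit, X, pheno)
        assert max_res <= 10 * tol

    def test_perturbation_increases_residual(self):
        X, pheno, groups = seeded_instance(seed=3)
        lam = 0.3 * lambda_max(X, pheno, groups, 0.5)
        fit = fit_sgl(X, pheno, groups, 0.5, lam=lam, tol=1e-8)
        _, base = kkt_check(fit, X, pheno)
        j = int(np.argmax(np.abs(fit.coef)))
        fit.coef = fit.coef.copy()
        fit.coef[j] += 0.1
        _, perturbed = kkt_check(fit, X, pheno)
        assert perturbed > base

    def test_null_fit_above_lambda_max_has_zero_residual(self):
        X, pheno, groups = seeded_instance(seed=4)
        lmax = lambda_max(X, pheno, groups, 0.5)
        fit = fit_sgl(X, pheno, groups, 0.5, lam=lmax * 1.05, tol=1e-8)
        res, max_res = kkt_check(fit, X, pheno)
        assert np.all(res == 0.0)


class TestCrossValidate:
    def _instance(self, seed=0):
        rng = np.random.default_rng(seed)
        n, N = 40, 24
        groups = np.repeat(np.arange(4), 6)
        latent = rng.normal(size=n)
        X = rng.normal(size=(n, N)) * 0.5
        X[:, :6] += latent[:, None]
        y = (latent + rng.normal(scale=0.5, size=n) > 0).astype(float)
        return X, binary_pheno(y), groups

    def test_single_alpha_selected_verbatim(self):
        X, pheno, groups = self._instance()
        cv = cross_validate(X, pheno, groups, alpha_grid=(0.4,), n_lambda=6,
                            n_folds=4, seed=0)
        assert cv.alpha_best == 0.4

    def test_same_seed_reproducible(self):
        X, pheno, groups = self._instance()
        a = cross_validate(X, pheno, groups, alpha_grid=(0.2, 0.8),
                           n_lambda=6, n_folds=4, seed=3)
        b = cross_validate(X, pheno, groups, alpha_grid=(0.2, 0.8),
                           n_lambda=6, n_folds=4, seed=3)
        assert a.alpha_best == b.alpha_best
        assert a.lambda_best == b.lambda_best
        np.testing.assert_array_equal(a.fold_ids, b.fold_ids)
        np.testing.assert_array_equal(a.mean_loss, b.mean_loss)

    def test_folds_stratified_and_balanced(self):
        X, pheno, groups = self._instance(seed=2)
        cv = cross_validate(X, pheno, groups, alpha_grid=(0.5,), n_lambda=4,
                            n_folds=5, seed=1)
        sizes = np.bincount(cv.fold_ids)
        assert sizes.max() - sizes.min() <= 1
        overall = pheno.y.mean()
        for k in range(5):
            frac = pheno.y[cv.fold_ids == k].mean()
            assert abs(frac - overall) < 0.3

    def test_signal_beats_null_and_selects_signal_group(self):
        X, pheno, groups = self._instance(seed=5)
        cv = cross_validate(X, pheno, groups, alpha_grid=(0.1, 0.9),
                            n_lambda=10, n_folds=4, seed=5)
        fit = fit_sgl(X, pheno, groups, cv.alpha_best, lam=cv.lambda_best,
                      tol=1e-6)
        active = np.flatnonzero(fit.coef != 0)
        assert active.size > 0
        assert np.all(active < 6) or np.mean(active < 6) > 0.5
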