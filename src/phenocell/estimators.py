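"""Sklearn-style estimators wrapping the sparse group lasso core.

All estimators take a ``groups`` parameter: an integer label per design
column, non-decreasing (group blocks contiguous). Columns are centered
and unit-scaled before fitting by default (penalties are scale
sensitive); coefficients are reported on the original scale, which
leaves their signs — and hence the cell classification — unchanged.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import _solver
from .containers import PhenotypeVector
from .errors import ValidationError


def _standardize(X):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd_safe, mean, sd_safe


class _SGLBase(BaseEstimator):
    def __init__(self, groups=None, alpha=0.5, lam=0.1, standardize=True,
                 tol=1e-5, max_iter=2000):
        self.groups = groups
        self.alpha = alpha
        self.lam = lam
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter

    def _prepare(self, X):
        X = check_array(X, dtype=float)
        groups = (np.zeros(X.shape[1], dtype=int) if self.groups is None
                  else np.asarray(self.groups, dtype=int))
        if groups.shape[0] != X.shape[1]:
            raise ValidationError("groups length must equal n_features")
        if self.standardize:
            Xs, mean, sd = _standardize(X)
        else:
            Xs, mean, sd = X, np.zeros(X.shape[1]), np.ones(X.shape[1])
        return Xs, groups, mean, sd

    def _store(self, res, mean, sd, has_intercept):
        beta_std = res["beta"]
        self.coef_ = beta_std / sd
        if has_intercept:
            self.intercept_ = float(res["intercept"] - np.sum(mean * self.coef_))
        else:
            self.intercept_ = 0.0
        self.coef_std_ = beta_std
        self.n_iter_ = res["n_iter"]
        self.objective_ = res["objective"]
        self.kkt_residual_ = res["kkt"]


class SparseGroupLassoClassifier(_SGLBase, ClassifierMixin):
    """Binary sparse group lasso with logistic loss and unpenalized intercept.

    Parameters
    ----------
    groups : array-like of int, per feature (non-decreasing)
    alpha : float in [0, 1]
        Mix between lasso (1) and group lasso (0).
    lam : float
        Overall penalty strength.
    standardize : bool
        Center/scale columns before fitting (coefficients are returned on
        the original scale).

    Attributes
    ----------
    coef_ : ndarray (n_features,)
    intercept_ : float
    n_iter_, objective_, kkt_residual_ : solver diagnostics
    """

    def fit(self, X, y):
        Xs, groups, mean, sd = self._prepare(X)
        y = np.asarray(y, dtype=float).ravel()
        self.classes_ = np.unique(y)
        model = _solver.LogisticModel(y)
        res = _solver.fit_sgl_path(Xs, model, groups, self.alpha,
                                   [float(self.lam)], tol=self.tol,
                                   max_iter=self.max_iter)[0]
        self._store(res, mean, sd, True)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        from scipy.special import expit

        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(float)


class SparseGroupLassoCox(_SGLBase):
    """Sparse group lasso Cox proportional hazards (Breslow ties).

    ``y`` in :meth:`fit` is a (n, 2) array of (time, status) with status 1
    for an observed event. There is no intercept (absorbed by the
    baseline hazard); ``predict`` returns the linear risk score.
    """

    def fit(self, X, y):
        Xs, groups, mean, sd = self._prepare(X)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValidationError("survival y must be (n, 2): time, status")
        model = _solver.CoxModel(y[:, 0], y[:, 1])
        res = _solver.fit_sgl_path(Xs, model, groups, self.alpha,
                                   [float(self.lam)], tol=self.tol,
                                   max_iter=self.max_iter)[0]
        self._store(res, mean, sd, False)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_


class SparseGroupLassoCV(_SGLBase):
    """Cross-validated (alpha, lambda) selection plus a final refit.

    Runs, for every alpha in ``alpha_grid``, a log-spaced lambda path of
    ``n_lambda`` values from lambda_max down to 0.01*lambda_max, scores
    each pair by k-fold cross-validated loss, picks the minimizer (ties
    toward larger lambda then smaller alpha) and refits on all samples.

    Attributes
    ----------
    alpha_, lambda_ : selected pair
    coef_, intercept_ : refit coefficients on the original scale
    cv_result_ : :class:`phenocell.sgl.CVResult`
    """

    def __init__(self, groups=None, alpha_grid=(0.5,), n_lambda=20, cv=5,
                 mode="binary", standardize=True, tol=1e-5, max_iter=2000,
                 random_state=0, fix_alpha=None, fix_lambda=None,
                 selection="1se"):
        self.groups = groups
        self.alpha_grid = alpha_grid
        self.n_lambda = n_lambda
        self.cv = cv
        self.mode = mode
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.fix_alpha = fix_alpha
        self.fix_lambda = fix_lambda
        self.selection = selection

    def fit(self, X, y):
        from . import sgl as sgl_mod

        Xs, groups, mean, sd = self._prepare(X)
        y = np.asarray(y, dtype=float)
        if self.mode == "binary":
            pheno = PhenotypeVector(
                [str(i) for i in range(Xs.shape[0])], "binary", y=y.ravel())
        else:
            pheno = PhenotypeVector(
                [str(i) for i in range(Xs.shape[0])], "survival",
                time=y[:, 0], status=y[:, 1])
        model = _solver.make_model(pheno)
        slices = _solver.group_slices(groups)

        if self.fix_alpha is not None and self.fix_lambda is not None:
            self.alpha_ = float(self.fix_alpha)
            self.lambda_ = float(self.fix_lambda)
            self.cv_result_ = None
        else:
            grid = ([self.fix_alpha] if self.fix_alpha is not None
                    else list(self.alpha_grid))
            cvres = sgl_mod.cross_validate(
                Xs, pheno, group_labels=groups, alpha_grid=grid,
                n_lambda=self.n_lambda, n_folds=self.cv,
                seed=self.random_state, tol=self.tol, max_iter=self.max_iter,
                selection=self.selection)
            self.cv_result_ = cvres
            self.alpha_ = cvres.alpha_best
            self.lambda_ = (cvres.lambda_best if self.fix_lambda is None
                            else float(self.fix_lambda))

        # refit on the full data, warm-starting down the path to lambda_
        lmax = _solver.lambda_max(Xs, model, slices, self.alpha_)
        path = [l for l in sgl_mod._lambda_path(lmax, self.n_lambda)
                if l > self.lambda_ * (1 + 1e-12)]
        full_path = np.array(path + [self.lambda_])
        res = _solver.fit_sgl_path(Xs, model, groups, self.alpha_, full_path,
                                   tol=self.tol, max_iter=self.max_iter)[-1]
        self._store(res, mean, sd, model.has_intercept)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_ + self.intercept_
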