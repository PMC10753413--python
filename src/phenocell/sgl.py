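"""Sparse group lasso over the correlation design matrix.

Public operations: the two loss functions, the composite objective,
``lambda_max``, ``fit_sgl``, ``kkt_check`` and ``cross_validate``. These
are thin wrappers over the numerical core in :mod:`phenocell._solver`;
the sklearn-style estimator classes live in :mod:`phenocell.estimators`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from . import _solver
from .containers import CorrelationMatrix, PhenotypeVector
from .errors import FoldError, ValidationError

log = logging.getLogger("phenocell")


@dataclass
class SGLFit:
    """A fitted sparse group lasso model over cells.

    ``coef`` is in the design's (group-contiguous) column order;
    ``cell_ids``/``group_labels`` give the matching identifiers.
    """

    cell_ids: list
    group_labels: np.ndarray
    coef: np.ndarray
    intercept: float
    alpha: float
    lam: float
    n_iter: int = 0
    objective: float = float("nan")
    kkt_residual: float = float("nan")
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def group_sizes(self):
        return np.bincount(np.asarray(self.group_labels, dtype=int))

    @property
    def n_selected(self):
        return int(np.count_nonzero(self.coef))


@dataclass
class CVResult:
    """Cross-validation surface over the (alpha, lambda) grid."""

    alphas: np.ndarray  # flattened grid, one row per (alpha, lambda)
    lambdas: np.ndarray
    mean_loss: np.ndarray
    se_loss: np.ndarray
    fold_losses: np.ndarray  # grid x folds held-out losses
    fold_ids: np.ndarray  # per-sample fold assignment
    alpha_best: float
    lambda_best: float
    seed: int


def _design(X):
    if isinstance(X, CorrelationMatrix):
        return X.values, X.group_labels, list(X.cell_ids)
    raise ValidationError("expected a CorrelationMatrix design")


def _check_dims(values, pheno):
    if values.shape[0] != pheno.n_samples:
        raise ValidationError(
            f"design has {values.shape[0]} rows but phenotype has "
            f"{pheno.n_samples} samples"
        )


def logistic_loss(X, pheno: PhenotypeVector, beta, intercept=0.0):
    """Binary negative log-likelihood sum_i [log(1+e^eta_i) - y_i eta_i]."""
    values, _, _ = _design(X) if isinstance(X, CorrelationMatrix) else (np.asarray(X, float), None, None)
    if pheno.mode != "binary":
        raise ValidationError("logistic loss requires binary phenotype")
    _check_dims(values, pheno)
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != values.shape[1]:
        raise ValidationError("coefficient length does not match design columns")
    model = _solver.LogisticModel(pheno.y)
    return model.value(values @ beta + intercept)


def cox_loss(X, pheno: PhenotypeVector, beta):
    """Breslow negative log partial likelihood (closed risk sets)."""
    values, _, _ = _design(X) if isinstance(X, CorrelationMatrix) else (np.asarray(X, float), None, None)
    if pheno.mode != "survival":
        raise ValidationError("Cox loss requires survival phenotype")
    _check_dims(values, pheno)
    beta = np.asarray(beta, dtype=float)
    model = _solver.CoxModel(pheno.time, pheno.status)
    return model.value(values @ beta)


def sgl_objective(loss_value, beta, n, lam, alpha, group_sizes):
    """(1/n) loss + lambda[(1-alpha) sum_l sqrt(p_l)||b_l||_2 + alpha||b||_1]."""
    return _solver.sgl_objective(loss_value, beta, n, lam, alpha, group_sizes)


def lambda_max(X, pheno, group_labels=None, alpha=0.5):
    """Smallest lambda at which the all-zero coefficient vector is optimal."""
    if isinstance(X, CorrelationMatrix):
        values, labels, _ = _design(X)
    else:
        values, labels = np.asarray(X, dtype=float), np.asarray(group_labels)
    model = _solver.make_model(pheno)
    _check_dims(values, pheno)
    return _solver.lambda_max(values, model, _solver.group_slices(labels), alpha)


def fit_sgl(X, pheno, group_labels=None, alpha=0.5, lam=None, tol=1e-5,
            max_iter=2000):
    """Fit the SGL at a single lambda or along a decreasing lambda path.

    Returns one :class:`SGLFit` for a scalar ``lam``, else a list of fits
    (warm-started along the path).
    """
    if isinstance(X, CorrelationMatrix):
        values, labels, cell_ids = _design(X)
    else:
        values = np.asarray(X, dtype=float)
        labels = np.asarray(group_labels)
        cell_ids = [str(i) for i in range(values.shape[1])]
    model = _solver.make_model(pheno)
    _check_dims(values, pheno)
    scalar = np.isscalar(lam)
    lams = np.atleast_1d(np.asarray(lam, dtype=float))
    res = _solver.fit_sgl_path(values, model, labels, alpha, lams, tol=tol,
                               max_iter=max_iter)
    fits = [
        SGLFit(
            cell_ids=cell_ids,
            group_labels=np.asarray(labels),
            coef=r["beta"],
            intercept=r["intercept"] if r["intercept"] is not None else 0.0,
            alpha=r["alpha"],
            lam=r["lam"],
            n_iter=r["n_iter"],
            objective=r["objective"],
            kkt_residual=r["kkt"],
            objective_trace=r["objective_trace"],
        )
        for r in res
    ]
    return fits[0] if scalar else fits


def kkt_check(fit: SGLFit, X, pheno):
    """Per-group subdifferential residuals of a fitted model."""
    if isinstance(X, CorrelationMatrix):
        values, labels, _ = _design(X)
    else:
        values = np.asarray(X, dtype=float)
        labels = fit.group_labels
    model = _solver.make_model(pheno)
    b0 = fit.intercept if model.has_intercept else None
    res = _solver.kkt_residuals(
        values, model, _solver.group_slices(labels), fit.coef, b0,
        fit.lam, fit.alpha,
    )
    return res, float(res.max())


def _lambda_path(lmax, n_lambda):
    return np.logspace(np.log10(lmax), np.log10(0.01 * lmax), n_lambda)


def _draw_folds(pheno, n_folds, seed):
    """Seeded folds; stratified on labels in binary mode. Re-draws until
    every training part has both classes (binary) / at least one event
    (survival)."""
    n = pheno.n_samples
    if n < n_folds:
        raise FoldError(f"{n} samples cannot be split into {n_folds} folds")
    for attempt in range(100):
        rs = (seed + 7919 * attempt) % (2 ** 31)
        if pheno.mode == "binary":
            splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                       random_state=rs)
            splits = list(splitter.split(np.zeros(n), pheno.y))
            ok = all(len(np.unique(pheno.y[tr])) == 2 for tr, _ in splits)
        else:
            splitter = KFold(n_splits=n_folds, shuffle=True, random_state=rs)
            splits = list(splitter.split(np.zeros(n)))
            ok = all(pheno.status[tr].sum() >= 1 for tr, _ in splits)
        if ok:
            fold_ids = np.empty(n, dtype=int)
            for k, (_, te) in enumerate(splits):
                fold_ids[te] = k
            return splits, fold_ids
    raise FoldError("could not draw valid cross-validation folds in 100 attempts")


def _heldout_loss_binary(values, pheno, tr, te, fit_res):
    model = _solver.LogisticModel(pheno.y[te])
    eta = values[te] @ fit_res["beta"] + fit_res["intercept"]
    return model.value(eta) / te.shape[0]


def _heldout_loss_survival(values, pheno, tr, te, fit_res, model_full, model_tr):
    """Verweij & van Houwelingen: l_full(beta) - l_train(beta), per
    held-out sample (so the scale matches the binary per-sample loss)."""
    beta = fit_res["beta"]
    full = model_full.value(values @ beta)
    train = model_tr.value(values[tr] @ beta)
    return (full - train) / te.shape[0]


def _select_pair(alphas, lambdas, means, fold_losses, selection, paired):
    """Pick (alpha*, lambda*) from the CV surface.

    ``selection='1se'`` (default) treats every pair whose mean loss lies
    within one standard error of the minimizer as tied with it, then
    breaks ties toward larger lambda and smaller alpha — the usual guard
    against chasing noise in the CV estimate. ``'min'`` takes the exact
    minimizer with the same tie-breaking at numerical resolution.

    The SE estimator follows the structure of the loss statistic. Binary
    fold losses are per-sample mean log-likelihoods and exchangeable
    across folds, so the classic unpaired SE at the minimizer applies
    (``paired=False``). The survival partial-likelihood deviance carries
    a fold-composition offset that is common to every pair within a
    fold, so only the fold-wise paired difference against the minimizer
    has a meaningful SE (``paired=True``).
    """
    i_min = min(range(len(means)),
                key=lambda i: (means[i], -lambdas[i], alphas[i]))
    if selection == "min":
        cand = np.flatnonzero(means <= means[i_min] + 1e-12)
    elif selection == "1se":
        k = fold_losses.shape[1]
        if paired:
            diffs = fold_losses - fold_losses[i_min]
            se = diffs.std(axis=1, ddof=1) / np.sqrt(k)
            cand = np.flatnonzero(means - means[i_min] <= se + 1e-12)
        else:
            se_min = fold_losses[i_min].std(ddof=1) / np.sqrt(k)
            cand = np.flatnonzero(means <= means[i_min] + se_min + 1e-12)
    else:
        raise ValidationError("selection must be 'min' or '1se'")
    return cand[min(range(len(cand)),
                    key=lambda i: (-lambdas[cand[i]], alphas[cand[i]]))]


def cross_validate(X, pheno, group_labels=None, alpha_grid=(0.5,), n_lambda=20,
                   n_folds=5, seed=0, tol=1e-5, max_iter=2000, fold_tol=None,
                   selection="1se"):
    """Select (alpha*, lambda*) by k-fold cross-validation.

    For each alpha a 20-point (by default) log-spaced lambda path runs from
    lambda_max(alpha) down to 0.01*lambda_max. Held-out loss is the mean
    binary negative log-likelihood, or the partial-likelihood deviance
    contribution ("full minus leave-fold-out") in survival mode. Ties are
    broken toward larger lambda, then smaller alpha.

    Fold fits use a relaxed tolerance (``fold_tol``, default 1e-3): the
    held-out loss is a noisy estimate, so solving each fold to the
    final-refit precision buys nothing. The final model is refit at the
    full tolerance by the caller.
    """
    if isinstance(X, CorrelationMatrix):
        values, labels, _ = _design(X)
    else:
        values = np.asarray(X, dtype=float)
        labels = np.asarray(group_labels)
    alpha_grid = [float(a) for a in alpha_grid]
    if not alpha_grid:
        raise ValidationError("alpha grid must be non-empty")
    _check_dims(values, pheno)
    if fold_tol is None:
        fold_tol = max(10.0 * tol, 1e-3)
    splits, fold_ids = _draw_folds(pheno, n_folds, seed)
    model_full = _solver.make_model(pheno)
    slices = _solver.group_slices(labels)

    rows = []
    for a in alpha_grid:
        lmax = _solver.lambda_max(values, model_full, slices, a)
        path = _lambda_path(lmax, n_lambda)
        fold_losses = np.zeros((n_folds, n_lambda))
        for k, (tr, te) in enumerate(splits):
            sub = pheno.subset(tr)
            model_tr = _solver.make_model(sub)
            res = _solver.fit_sgl_path(values[tr], model_tr, labels, a, path,
                                       tol=fold_tol, max_iter=max_iter)
            for j, r in enumerate(res):
                if pheno.mode == "binary":
                    fold_losses[k, j] = _heldout_loss_binary(values, pheno, tr,
                                                             te, r)
                else:
                    fold_losses[k, j] = _heldout_loss_survival(
                        values, pheno, tr, te, r, model_full, model_tr)
        mean = fold_losses.mean(axis=0)
        se = fold_losses.std(axis=0, ddof=1) / np.sqrt(n_folds)
        for j in range(n_lambda):
            rows.append((a, path[j], mean[j], se[j], fold_losses[:, j].copy()))

    alphas = np.array([r[0] for r in rows])
    lambdas = np.array([r[1] for r in rows])
    means = np.array([r[2] for r in rows])
    ses = np.array([r[3] for r in rows])
    folds_mat = np.array([r[4] for r in rows])
    best = _select_pair(alphas, lambdas, means, folds_mat, selection,
                        paired=(pheno.mode == "survival"))
    return CVResult(
        alphas=alphas, lambdas=lambdas, mean_loss=means, se_loss=ses,
        fold_losses=folds_mat, fold_ids=fold_ids,
        alpha_best=float(alphas[best]), lambda_best=float(lambdas[best]),
        seed=seed,
    )
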