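"""Numerical core of the sparse group lasso.

Minimizes, over coefficient vectors beta with contiguous group blocks,

    (1/n) * loss(beta) + lambda * [ (1-alpha) * sum_l sqrt(p_l) ||beta_l||_2
                                    + alpha * ||beta||_1 ]

for a logistic (binary phenotype) or Cox partial-likelihood (survival)
loss, by blockwise descent: each group is first screened against the
group-zero subdifferential condition and, if active, minimized by a
monotone accelerated proximal gradient method with backtracking line
search. Solutions along a decreasing lambda path are warm-started.

The sweep kernels are numba-compiled; the group blocks are addressed
through a row-contiguous transpose of the design so every matrix-vector
product hits BLAS.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ConvergenceError, ValidationError

_MODE_LOGISTIC = 0
_MODE_COX = 1


# ---------------------------------------------------------------------------
# jitted loss primitives (value / gradient in the linear predictor eta)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _loss_value(eta, mode, y, order, block_end, status_sorted, d_block):
    n = eta.shape[0]
    if mode == _MODE_LOGISTIC:
        s = 0.0
        for i in range(n):
            e = eta[i]
            if e > 0.0:
                s += e + np.log1p(np.exp(-e)) - y[i] * e
            else:
                s += np.log1p(np.exp(e)) - y[i] * e
        return s
    # Cox, Breslow ties: samples pre-sorted by decreasing time
    mx = eta[0]
    for i in range(1, n):
        if eta[i] > mx:
            mx = eta[i]
    val = 0.0
    csum = 0.0
    bi = 0
    for pos in range(n):
        e = eta[order[pos]]
        csum += np.exp(e - mx)
        if pos == block_end[bi]:
            val += d_block[bi] * (mx + np.log(csum))
            bi += 1
        if status_sorted[pos] == 1.0:
            val -= e
    return val


@njit(cache=True)
def _loss_grad(eta, mode, y, order, block_end, block_of, status_sorted,
               d_block, out):
    n = eta.shape[0]
    if mode == _MODE_LOGISTIC:
        for i in range(n):
            e = eta[i]
            if e >= 0.0:
                p = 1.0 / (1.0 + np.exp(-e))
            else:
                z = np.exp(e)
                p = z / (1.0 + z)
            out[i] = p - y[i]
        return
    mx = eta[0]
    for i in range(1, n):
        if eta[i] > mx:
            mx = eta[i]
    n_blocks = block_end.shape[0]
    L = np.empty(n_blocks)
    csum = 0.0
    bi = 0
    for pos in range(n):
        csum += np.exp(eta[order[pos]] - mx)
        if pos == block_end[bi]:
            L[bi] = np.log(csum)  # log-sum-exp minus mx
            bi += 1
    # factor_b = sum over blocks b' >= b of d_b' / exp(L_b' + mx)
    factor = np.empty(n_blocks)
    acc = 0.0
    for b in range(n_blocks - 1, -1, -1):
        acc += d_block[b] * np.exp(-L[b])
        factor[b] = acc
    for pos in range(n):
        j = order[pos]
        out[j] = np.exp(eta[j] - mx) * factor[block_of[pos]] - status_sorted[pos]


@njit(cache=True)
def _prox_group(v, t, lam, alpha, sqrt_p, out):
    """Prox of t*[lam*alpha*||.||_1 + lam*(1-alpha)*sqrt_p*||.||_2]."""
    thr = t * lam * alpha
    nrm = 0.0
    for j in range(v.shape[0]):
        u = v[j]
        if u > thr:
            u -= thr
        elif u < -thr:
            u += thr
        else:
            u = 0.0
        out[j] = u
        nrm += u * u
    nrm = np.sqrt(nrm)
    shrink = t * lam * (1.0 - alpha) * sqrt_p
    if nrm <= shrink:
        for j in range(out.shape[0]):
            out[j] = 0.0
    else:
        scale = 1.0 - shrink / nrm
        for j in range(out.shape[0]):
            out[j] *= scale
    return out


@njit(cache=True)
def _block_penalty(b, lam, alpha, sqrt_p):
    l1 = 0.0
    l2 = 0.0
    for j in range(b.shape[0]):
        l1 += abs(b[j])
        l2 += b[j] * b[j]
    return lam * (alpha * l1 + (1.0 - alpha) * sqrt_p * np.sqrt(l2))


@njit(cache=True)
def _solve_group_kernel(XTl, b, eta_rest, n, lam, alpha, sqrt_p, L0, tol,
                        max_inner, mode, y, order, block_end, block_of,
                        status_sorted, d_block, grad_buf):
    """Monotone accelerated proximal gradient on one group block.

    ``XTl`` is the (p, n) row-contiguous block of the transposed design.
    The step starts at 1/L0 and backtracks on the smooth majorization.
    """
    p = XTl.shape[0]
    t = 1.0 / L0
    x = b.copy()
    eta_x = eta_rest + np.dot(x, XTl)
    fx = _loss_value(eta_x, mode, y, order, block_end, status_sorted,
                     d_block) / n
    hx = fx + _block_penalty(x, lam, alpha, sqrt_p)
    yv = x.copy()
    eta_y = eta_x.copy()
    fy = fx
    momentum = 1.0
    cand = np.empty(p)
    for _ in range(max_inner):
        _loss_grad(eta_y, mode, y, order, block_end, block_of, status_sorted,
                   d_block, grad_buf)
        g = np.dot(XTl, grad_buf) / n
        f_cand = 0.0
        eta_cand = eta_y
        for _bt in range(60):
            _prox_group(yv - t * g, t, lam, alpha, sqrt_p, cand)
            diff = cand - yv
            eta_cand = eta_y + np.dot(diff, XTl)
            f_cand = _loss_value(eta_cand, mode, y, order, block_end,
                                 status_sorted, d_block) / n
            sq = 0.0
            lin = 0.0
            for j in range(p):
                lin += g[j] * diff[j]
                sq += diff[j] * diff[j]
            if f_cand <= fy + lin + sq / (2.0 * t) + 1e-14:
                break
            t *= 0.5
        h_cand = f_cand + _block_penalty(cand, lam, alpha, sqrt_p)
        if h_cand <= hx + 1e-15:
            change = 0.0
            for j in range(p):
                c = abs(cand[j] - x[j])
                if c > change:
                    change = c
            new_momentum = (1.0 + np.sqrt(1.0 + 4.0 * momentum * momentum)) / 2.0
            accel = (momentum - 1.0) / new_momentum
            yv = cand + accel * (cand - x)
            x = cand.copy()
            hx = h_cand
            eta_x = eta_cand.copy()
            eta_y = eta_rest + np.dot(yv, XTl)
            fy = _loss_value(eta_y, mode, y, order, block_end, status_sorted,
                             d_block) / n
            momentum = new_momentum
            if change < tol:
                break
        else:
            # monotone fallback: plain prox step from x, restart momentum
            _loss_grad(eta_x, mode, y, order, block_end, block_of,
                       status_sorted, d_block, grad_buf)
            g = np.dot(XTl, grad_buf) / n
            fx = _loss_value(eta_x, mode, y, order, block_end, status_sorted,
                             d_block) / n
            for _bt in range(60):
                _prox_group(x - t * g, t, lam, alpha, sqrt_p, cand)
                diff = cand - x
                eta_cand = eta_x + np.dot(diff, XTl)
                f_cand = _loss_value(eta_cand, mode, y, order, block_end,
                                     status_sorted, d_block) / n
                sq = 0.0
                lin = 0.0
                for j in range(p):
                    lin += g[j] * diff[j]
                    sq += diff[j] * diff[j]
                if f_cand <= fx + lin + sq / (2.0 * t) + 1e-14:
                    break
                t *= 0.5
            h_cand = f_cand + _block_penalty(cand, lam, alpha, sqrt_p)
            change = 0.0
            for j in range(p):
                c = abs(cand[j] - x[j])
                if c > change:
                    change = c
            if h_cand > hx + 1e-15 and change < 1e-15:
                break
            x = cand.copy()
            hx = h_cand
            eta_x = eta_cand.copy()
            yv = x.copy()
            eta_y = eta_x.copy()
            fy = f_cand
            momentum = 1.0
            if change < tol:
                break
    return x, eta_x


@njit(cache=True)
def _kkt_kernel(XT, starts, ends, beta, eta, lam, alpha, n, mode, y, order,
                block_end, block_of, status_sorted, d_block):
    grad_eta = np.empty(eta.shape[0])
    _loss_grad(eta, mode, y, order, block_end, block_of, status_sorted,
               d_block, grad_eta)
    n_groups = starts.shape[0]
    res = np.zeros(n_groups)
    for li in range(n_groups):
        s, e = starts[li], ends[li]
        p = e - s
        sqrt_p = np.sqrt(p)
        all_zero = True
        for j in range(s, e):
            if beta[j] != 0.0:
                all_zero = False
                break
        g = np.dot(XT[s:e], grad_eta) / n
        if all_zero:
            thr = lam * alpha
            nrm = 0.0
            for j in range(p):
                u = abs(g[j]) - thr
                if u > 0.0:
                    nrm += u * u
            r = np.sqrt(nrm) - lam * (1.0 - alpha) * sqrt_p
            res[li] = r if r > 0.0 else 0.0
        else:
            nrm = 0.0
            for j in range(s, e):
                nrm += beta[j] * beta[j]
            nrm = np.sqrt(nrm)
            r = 0.0
            for j in range(p):
                bj = beta[s + j]
                if bj != 0.0:
                    sgn = 1.0 if bj > 0 else -1.0
                    v = abs(g[j] + lam * alpha * sgn
                            + lam * (1.0 - alpha) * sqrt_p * bj / nrm)
                else:
                    v = abs(g[j]) - lam * alpha
                    if v < 0.0:
                        v = 0.0
                if v > r:
                    r = v
            res[li] = r
    return res


@njit(cache=True)
def _intercept_newton(b0, eta, n, y, tol):
    """Damped Newton on the unpenalized logistic intercept."""
    for _ in range(20):
        gsum = 0.0
        hsum = 0.0
        f0 = 0.0
        for i in range(n):
            e = eta[i]
            if e >= 0.0:
                p = 1.0 / (1.0 + np.exp(-e))
                f0 += e + np.log1p(np.exp(-e)) - y[i] * e
            else:
                z = np.exp(e)
                p = z / (1.0 + z)
                f0 += np.log1p(z) - y[i] * e
            gsum += p - y[i]
            hsum += p * (1.0 - p)
        if abs(gsum) / n < 0.1 * tol:
            break
        if hsum < 1e-10:
            hsum = 1e-10
        step = gsum / hsum
        for _bt in range(40):
            f1 = 0.0
            for i in range(n):
                e = eta[i] - step
                if e > 0.0:
                    f1 += e + np.log1p(np.exp(-e)) - y[i] * e
                else:
                    f1 += np.log1p(np.exp(e)) - y[i] * e
            if f1 <= f0 + 1e-14:
                break
            step *= 0.5
        b0 -= step
        for i in range(n):
            eta[i] -= step
    return b0


@njit(cache=True)
def _path_kernel(XT, starts, ends, alpha, lambdas, tol, max_iter, mode, y,
                 order, block_end, block_of, status_sorted, d_block, beta,
                 b0, has_intercept, Lg, inner_tol, max_inner):
    """Warm-started blockwise descent over a decreasing lambda path.

    Returns (betas, intercepts, n_iters, kkts, traces, trace_lens,
    converged flags).
    """
    n_lam = lambdas.shape[0]
    N = beta.shape[0]
    n = XT.shape[1]
    n_groups = starts.shape[0]
    betas = np.empty((n_lam, N))
    intercepts = np.empty(n_lam)
    n_iters = np.zeros(n_lam, dtype=np.int64)
    kkts = np.empty(n_lam)
    traces = np.empty((n_lam, max_iter))
    trace_lens = np.zeros(n_lam, dtype=np.int64)
    converged_flags = np.zeros(n_lam, dtype=np.int64)
    grad_buf = np.empty(n)
    sqrt_ps = np.empty(n_groups)
    for li in range(n_groups):
        sqrt_ps[li] = np.sqrt(ends[li] - starts[li])

    for lam_i in range(n_lam):
        lam = lambdas[lam_i]
        eta = np.dot(beta, XT)
        if has_intercept:
            for i in range(n):
                eta[i] += b0
        converged = False
        for sweep in range(max_iter):
            n_iters[lam_i] = sweep + 1
            max_change = 0.0
            if has_intercept:
                old = b0
                b0 = _intercept_newton(b0, eta, n, y, tol)
                c = abs(b0 - old)
                if c > max_change:
                    max_change = c
            for li in range(n_groups):
                s, e = starts[li], ends[li]
                bl = beta[s:e].copy()
                nonzero = False
                for j in range(bl.shape[0]):
                    if bl[j] != 0.0:
                        nonzero = True
                        break
                if nonzero:
                    eta_rest = eta - np.dot(bl, XT[s:e])
                else:
                    eta_rest = eta.copy()
                _loss_grad(eta_rest, mode, y, order, block_end, block_of,
                           status_sorted, d_block, grad_buf)
                g0 = np.dot(XT[s:e], grad_buf) / n
                thr = lam * alpha
                nrm = 0.0
                for j in range(g0.shape[0]):
                    u = abs(g0[j]) - thr
                    if u > 0.0:
                        nrm += u * u
                if np.sqrt(nrm) <= lam * (1.0 - alpha) * sqrt_ps[li] + 1e-15:
                    new = np.zeros(e - s)
                    eta = eta_rest
                else:
                    new, eta = _solve_group_kernel(
                        XT[s:e], bl, eta_rest, n, lam, alpha, sqrt_ps[li],
                        Lg[li], inner_tol, max_inner, mode, y, order,
                        block_end, block_of, status_sorted, d_block, grad_buf)
                for j in range(new.shape[0]):
                    c = abs(new[j] - bl[j])
                    if c > max_change:
                        max_change = c
                beta[s:e] = new
            # objective for the per-sweep trace
            loss = _loss_value(eta, mode, y, order, block_end, status_sorted,
                               d_block)
            pen = 0.0
            for li in range(n_groups):
                pen += _block_penalty(beta[starts[li]:ends[li]], lam, alpha,
                                      sqrt_ps[li])
            traces[lam_i, sweep] = loss / n + pen
            trace_lens[lam_i] = sweep + 1
            if max_change < tol:
                kkt = _kkt_kernel(XT, starts, ends, beta, eta, lam, alpha, n,
                                  mode, y, order, block_end, block_of,
                                  status_sorted, d_block).max()
                kkts[lam_i] = kkt
                if kkt <= 10.0 * tol:
                    converged = True
                    break
        if not converged:
            kkts[lam_i] = _kkt_kernel(XT, starts, ends, beta, eta, lam, alpha,
                                      n, mode, y, order, block_end, block_of,
                                      status_sorted, d_block).max()
        converged_flags[lam_i] = 1 if converged else 0
        betas[lam_i] = beta
        intercepts[lam_i] = b0
    return betas, intercepts, n_iters, kkts, traces, trace_lens, converged_flags


# ---------------------------------------------------------------------------
# loss model wrappers (shared with the public loss functions and CV)
# ---------------------------------------------------------------------------

_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_F = np.empty(0, dtype=np.float64)


class LogisticModel:
    """Negative log-likelihood of a logistic model, sum over samples."""

    smooth_bound = 0.25  # max second derivative of log(1+e^x)
    has_intercept = True
    mode = _MODE_LOGISTIC

    def __init__(self, y):
        self.y = np.ascontiguousarray(y, dtype=float)
        self.n = self.y.shape[0]
        self.order = _EMPTY_I
        self.block_end = _EMPTY_I
        self.block_of = _EMPTY_I
        self.status_sorted = _EMPTY_F
        self.d_block = _EMPTY_F

    def value(self, eta):
        return float(_loss_value(np.ascontiguousarray(eta, dtype=float),
                                 self.mode, self.y, self.order,
                                 self.block_end, self.status_sorted,
                                 self.d_block))

    def grad_eta(self, eta):
        out = np.empty(self.n)
        _loss_grad(np.ascontiguousarray(eta, dtype=float), self.mode, self.y,
                   self.order, self.block_end, self.block_of,
                   self.status_sorted, self.d_block, out)
        return out

    def null_eta(self):
        pbar = float(np.clip(self.y.mean(), 1e-12, 1 - 1e-12))
        b0 = np.log(pbar / (1.0 - pbar))
        return np.full(self.n, b0), b0


class CoxModel:
    """Breslow negative log partial likelihood as a function of eta.

    Samples are pre-sorted by decreasing survival time; tied times share
    a common risk-set denominator (Breslow). Risk sets are closed:
    R_i = {j : t_j >= t_i}.
    """

    smooth_bound = 0.25
    has_intercept = False
    mode = _MODE_COX

    def __init__(self, time, status):
        time = np.asarray(time, dtype=float)
        status = np.asarray(status, dtype=float)
        if status.sum() < 1:
            raise ValidationError("survival data contain no events")
        self.n = time.shape[0]
        self.y = _EMPTY_F
        self.order = np.ascontiguousarray(np.argsort(-time, kind="stable"))
        t_sorted = time[self.order]
        self.status_sorted = np.ascontiguousarray(status[self.order])
        change = np.flatnonzero(np.diff(t_sorted) != 0)
        self.block_end = np.ascontiguousarray(
            np.concatenate([change, [self.n - 1]]), dtype=np.int64)
        starts = np.concatenate([[0], change + 1])
        self.block_of = np.empty(self.n, dtype=np.int64)
        for b, (s, e) in enumerate(zip(starts, self.block_end)):
            self.block_of[s:e + 1] = b
        self.d_block = np.array([
            self.status_sorted[s:e + 1].sum()
            for s, e in zip(starts, self.block_end)
        ])

    def value(self, eta):
        return float(_loss_value(np.ascontiguousarray(eta, dtype=float),
                                 self.mode, self.y, self.order,
                                 self.block_end, self.status_sorted,
                                 self.d_block))

    def grad_eta(self, eta):
        out = np.empty(self.n)
        _loss_grad(np.ascontiguousarray(eta, dtype=float), self.mode, self.y,
                   self.order, self.block_end, self.block_of,
                   self.status_sorted, self.d_block, out)
        return out

    def null_eta(self):
        return np.zeros(self.n), None


def make_model(pheno):
    if pheno.mode == "binary":
        return LogisticModel(pheno.y)
    return CoxModel(pheno.time, pheno.status)


# ---------------------------------------------------------------------------
# penalty pieces and the public objective
# ---------------------------------------------------------------------------


def group_slices(group_labels):
    """Contiguous slices per group from a non-decreasing label vector."""
    labels = np.asarray(group_labels, dtype=int)
    if labels.size and np.any(np.diff(labels) < 0):
        raise ValidationError("group labels must be non-decreasing (contiguous)")
    bounds = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [labels.size]])
    return [slice(int(s), int(e)) for s, e in zip(starts, ends)]


def soft_threshold(v, t):
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def penalty_value(beta, slices, lam, alpha):
    group_part = sum(
        np.sqrt(sl.stop - sl.start) * np.linalg.norm(beta[sl]) for sl in slices
    )
    return lam * ((1.0 - alpha) * group_part + alpha * np.abs(beta).sum())


def sgl_objective(loss_value, beta, n, lam, alpha, group_sizes):
    """(1/n) loss + lambda[(1-alpha) sum sqrt(p_l) ||b_l|| + alpha ||b||_1]."""
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must lie in [0, 1]")
    if lam < 0:
        raise ValidationError("lambda must be non-negative")
    beta = np.asarray(beta, dtype=float)
    sizes = np.asarray(group_sizes, dtype=int)
    if sizes.sum() != beta.shape[0]:
        raise ValidationError("group sizes do not match coefficient length")
    pos = 0
    group_part = 0.0
    for p in sizes:
        group_part += np.sqrt(p) * np.linalg.norm(beta[pos:pos + p])
        pos += p
    return loss_value / n + lam * (
        (1.0 - alpha) * group_part + alpha * np.abs(beta).sum())


# ---------------------------------------------------------------------------
# lambda_max
# ---------------------------------------------------------------------------


def lambda_max(X, model, slices, alpha):
    """Smallest lambda at which beta = 0 is optimal.

    Uses the null-model gradient g of loss/n (intercept at the logit of
    the event rate for the logistic model) and solves, per group,
    ||soft(g_l, lam*alpha)||_2 = lam*(1-alpha)*sqrt(p_l) by bracketed
    one-dimensional root finding; the answer is the maximum over groups.
    """
    X = np.asarray(X, dtype=float)
    if np.allclose(X.std(axis=0), 0.0):
        raise ValidationError("all design columns are constant")
    eta0, _ = model.null_eta()
    g = X.T @ model.grad_eta(eta0) / model.n
    best = 0.0
    for sl in slices:
        gl = g[sl]
        p = sl.stop - sl.start
        gmax = float(np.abs(gl).max())
        if gmax == 0.0:
            continue
        if alpha >= 1.0:
            lam_l = gmax
        elif alpha <= 0.0:
            lam_l = float(np.linalg.norm(gl)) / np.sqrt(p)
        else:
            sqrt_p = np.sqrt(p)

            def f(lam):
                return float(
                    np.linalg.norm(soft_threshold(gl, lam * alpha))
                    - lam * (1.0 - alpha) * sqrt_p
                )

            hi = gmax / alpha
            if f(hi) >= 0:
                lam_l = hi
            else:
                lam_l = brentq(f, 0.0, hi, xtol=1e-10 * max(hi, 1.0), rtol=1e-12)
        best = max(best, lam_l)
    return best


# ---------------------------------------------------------------------------
# solver entry points
# ---------------------------------------------------------------------------


def kkt_residuals(X, model, slices, beta, b0, lam, alpha):
    """Per-group optimality residuals of the SGL subdifferential conditions."""
    X = np.asarray(X, dtype=float)
    XT = np.ascontiguousarray(X.T)
    beta = np.ascontiguousarray(beta, dtype=float)
    eta = np.dot(beta, XT)
    if b0 is not None:
        eta = eta + b0
    starts = np.array([sl.start for sl in slices], dtype=np.int64)
    ends = np.array([sl.stop for sl in slices], dtype=np.int64)
    return _kkt_kernel(XT, starts, ends, beta, np.ascontiguousarray(eta),
                       float(lam), float(alpha), model.n, model.mode, model.y,
                       model.order, model.block_end, model.block_of,
                       model.status_sorted, model.d_block)


def fit_sgl_path(X, model, group_labels, alpha, lambdas, tol=1e-5,
                 max_iter=2000, beta0=None, intercept0=None,
                 inner_tol=None, max_inner=200):
    """Fit the SGL at one or more lambda values (warm-started, decreasing).

    Returns a list of dicts with keys beta, intercept, lam, alpha,
    n_iter, objective, objective_trace, kkt.
    """
    X = np.asarray(X, dtype=float)
    n, N = X.shape
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must lie in [0, 1]")
    lambdas = np.atleast_1d(np.asarray(lambdas, dtype=float))
    if lambdas.size > 1 and np.any(np.diff(lambdas) >= 0):
        raise ValidationError("lambda path must be strictly decreasing")
    if np.any(lambdas < 0):
        raise ValidationError("lambda must be non-negative")
    slices = group_slices(group_labels)
    starts = np.array([sl.start for sl in slices], dtype=np.int64)
    ends = np.array([sl.stop for sl in slices], dtype=np.int64)
    if ends[-1] != N:
        raise ValidationError("group labels do not cover the design columns")
    XT = np.ascontiguousarray(X.T)
    # spectral-norm Lipschitz estimates for the group step sizes
    Lg = np.array([
        np.linalg.norm(X[:, sl], 2) ** 2 * model.smooth_bound / n + 1e-12
        for sl in slices
    ])
    beta = (np.zeros(N) if beta0 is None
            else np.ascontiguousarray(beta0, dtype=float).copy())
    if model.has_intercept:
        b0 = float(model.null_eta()[1] if intercept0 is None else intercept0)
    else:
        b0 = 0.0

    betas, intercepts, n_iters, kkts, traces, trace_lens, conv = _path_kernel(
        XT, starts, ends, float(alpha), lambdas, float(tol), int(max_iter),
        model.mode, model.y, model.order, model.block_end, model.block_of,
        model.status_sorted, model.d_block, beta, b0,
        model.has_intercept, Lg,
        float(0.1 * tol if inner_tol is None else inner_tol), int(max_inner))

    results = []
    for i in range(lambdas.shape[0]):
        if not conv[i] and kkts[i] > 10.0 * tol:
            raise ConvergenceError(
                f"SGL did not converge at lambda={lambdas[i]:g}, "
                f"alpha={alpha:g} after {max_iter} sweeps "
                f"(max KKT residual {kkts[i]:.3g})",
                n_iter=int(n_iters[i]), kkt=float(kkts[i]))
        tl = int(trace_lens[i])
        results.append(dict(
            beta=betas[i].copy(),
            intercept=float(intercepts[i]) if model.has_intercept else None,
            lam=float(lambdas[i]),
            alpha=float(alpha),
            n_iter=int(n_iters[i]),
            objective=float(traces[i, tl - 1]) if tl else float("nan"),
            objective_trace=traces[i, :tl].copy(),
            kkt=float(kkts[i]),
        ))
    return results
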