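"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — explicit loops, enumeration and
scalar minimization — and shares no code with the package internals it
checks.
"""

import itertools

import numpy as np
from scipy.optimize import minimize_scalar


def modularity_double_sum(A, labels, gamma):
    """Q by the literal O(n^2) double sum over ordered pairs."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    k = A.sum(axis=1)
    m = k.sum() / 2.0
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - gamma * k[i] * k[j] / (2.0 * m)
    return q / (2.0 * m)


def set_partitions(items):
    """All set partitions of a list (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_partition_exhaustive(A, gamma):
    """Maximum modularity over every set partition (tiny n only)."""
    n = A.shape[0]
    best_q, best_labels = -np.inf, None
    for part in set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for g, block in enumerate(part):
            for i in block:
                labels[i] = g
        q = modularity_double_sum(A, labels, gamma)
        if q > best_q + 1e-15:
            best_q, best_labels = q, labels
    return best_q, best_labels


def logistic_lasso_cd(X, y, lam, tol=1e-12, max_iter=5000):
    """Plain l1 logistic regression by cyclic exact coordinate descent.

    Minimizes (1/n) sum[log(1+e^eta) - y*eta] + lam*||beta||_1 with an
    unpenalized intercept, each coordinate by scalar minimization.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    b0 = 0.0

    def nll(eta):
        return np.sum(np.logaddexp(0.0, eta) - y * eta) / n

    eta = np.zeros(n)
    for _ in range(max_iter):
        delta = 0.0
        res = minimize_scalar(lambda v: nll(eta - b0 + v),
                              bracket=(b0 - 1.0, b0 + 1.0), method="brent",
                              options=dict(xtol=1e-14))
        eta += res.x - b0
        delta = max(delta, abs(res.x - b0))
        b0 = res.x
        for j in range(p):
            xj = X[:, j]
            old = beta[j]

            def f(v):
                return nll(eta + (v - old) * xj) + lam * abs(v)

            res = minimize_scalar(f, bracket=(old - 1.0, old + 1.0),
                                  method="brent", options=dict(xtol=1e-14))
            v = res.x
            # the l1 kink at zero defeats Brent; compare against v = 0
            if f(0.0) <= res.fun:
                v = 0.0
            eta += (v - old) * xj
            delta = max(delta, abs(v - old))
            beta[j] = v
        if delta < tol:
            break
    return beta, b0


def breslow_negative_log_partial_likelihood(X, beta, time, status):
    """Cox NLL with Breslow ties by explicit risk-set enumeration."""
    X = np.asarray(X, dtype=float)
    eta = X @ np.asarray(beta, dtype=float)
    total = 0.0
    for i in range(len(time)):
        if status[i] != 1:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        total += np.log(np.sum(np.exp(eta[risk]))) - eta[i]
    return total


def bh_rejections(pvals, q):
    """Benjamini-Hochberg step-up rejection set by direct enumeration."""
    p = np.asarray(pvals, dtype=float)
    m = p.shape[0]
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            k_star = rank
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_star]] = True
    return rejected


def bh_adjusted(pvals):
    """BH adjusted p-values by the textbook step-up recursion."""
    p = np.asarray(pvals, dtype=float)
    m = p.shape[0]
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
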