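"""Compiled EM inner loop.

The EM iteration is a few dozen small dense-algebra operations per step;
at the problem sizes this package targets (N in the hundreds, K ≤ 9, D ≤ 10)
interpreter overhead dominates a pure-numpy loop, so the whole
E-step/M-step alternation is compiled with numba. The numpy implementation
in :mod:`areamix.mixture` remains the reference path and is used when numba
is unavailable; both paths implement the identical update equations and the
test suite checks them against each other.

Status codes returned by the kernel: 0 = ok, 1 = degenerate component
(vanishing responsibility mass), 2 = non-finite density / singular
covariance.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap


# covariance kinds
SPHERICAL, DIAGONAL, FULL = 0, 1, 2

_LOG_2PI = np.log(2 * np.pi)


@njit(cache=True)
def _cholesky_lower(A, L):
    """Manual lower Cholesky of a small symmetric matrix. Returns success."""
    d = A.shape[0]
    for i in range(d):
        for j in range(i + 1):
            s = A[i, j]
            for m in range(j):
                s -= L[i, m] * L[j, m]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
        for j in range(i + 1, d):
            L[i, j] = 0.0
    return True


@njit(cache=True)
def _m_step_core(X, resp, kind, equal, var_floor, weights, means, covs):
    """In-place M-step. Returns (status, floored)."""
    n, d = X.shape
    k = resp.shape[1]
    floored = False
    for j in range(k):
        nk = 0.0
        for i in range(n):
            nk += resp[i, j]
        if nk < 1e-8:
            return 1, False
        weights[j] = nk / n
        for c in range(d):
            s = 0.0
            for i in range(n):
                s += resp[i, j] * X[i, c]
            means[j, c] = s / nk

    if kind == FULL:
        for j in range(k):
            for a in range(d):
                for b in range(a + 1):
                    s = 0.0
                    for i in range(n):
                        s += (resp[i, j] * (X[i, a] - means[j, a])
                              * (X[i, b] - means[j, b]))
                    covs[j, a, b] = s
                    covs[j, b, a] = s
        if equal:
            for a in range(d):
                for b in range(d):
                    s = 0.0
                    for j in range(k):
                        s += covs[j, a, b]
                    for j in range(k):
                        covs[j, a, b] = s / n
        else:
            for j in range(k):
                nk = weights[j] * n
                for a in range(d):
                    for b in range(d):
                        covs[j, a, b] /= nk
        if var_floor > 0.0:
            jmax = 1 if equal else k
            for j in range(jmax):
                vals, vecs = np.linalg.eigh(covs[j])
                if vals[0] < var_floor:
                    floored = True
                    for a in range(d):
                        if vals[a] < var_floor:
                            vals[a] = var_floor
                    for a in range(d):
                        for b in range(d):
                            s = 0.0
                            for m in range(d):
                                s += vecs[a, m] * vals[m] * vecs[b, m]
                            covs[j, a, b] = s
            if equal:
                for j in range(1, k):
                    for a in range(d):
                        for b in range(d):
                            covs[j, a, b] = covs[0, a, b]
        else:
            for j in range(k):
                for a in range(d):
                    if covs[j, a, a] <= 0.0:
                        return 2, floored
    else:
        # per-dimension weighted squared deviations
        dW = np.zeros((k, d))
        for j in range(k):
            for c in range(d):
                s = 0.0
                for i in range(n):
                    dv = X[i, c] - means[j, c]
                    s += resp[i, j] * dv * dv
                dW[j, c] = s
        var = np.empty((k, d))
        if kind == DIAGONAL:
            if equal:
                for c in range(d):
                    s = 0.0
                    for j in range(k):
                        s += dW[j, c]
                    for j in range(k):
                        var[j, c] = s / n
            else:
                for j in range(k):
                    nk = weights[j] * n
                    for c in range(d):
                        var[j, c] = dW[j, c] / nk
        else:  # SPHERICAL
            if equal:
                s = 0.0
                for j in range(k):
                    for c in range(d):
                        s += dW[j, c]
                v = s / (n * d)
                for j in range(k):
                    for c in range(d):
                        var[j, c] = v
            else:
                for j in range(k):
                    nk = weights[j] * n
                    s = 0.0
                    for c in range(d):
                        s += dW[j, c]
                    v = s / (nk * d)
                    for c in range(d):
                        var[j, c] = v
        for j in range(k):
            for c in range(d):
                if var_floor > 0.0:
                    if var[j, c] < var_floor:
                        floored = True
                        var[j, c] = var_floor
                elif var[j, c] <= 0.0:
                    return 2, floored
        for j in range(k):
            for a in range(d):
                for b in range(d):
                    covs[j, a, b] = 0.0
                covs[j, a, a] = var[j, a]
    return 0, floored


@njit(cache=True)
def _em_core(X, resp0, kind, equal, tol, max_iter, var_floor):
    """Full EM alternation. Returns (status, weights, means, covs, ll_hist,
    converged, n_iter, floored)."""
    n, d = X.shape
    k = resp0.shape[1]
    weights = np.empty(k)
    means = np.empty((k, d))
    covs = np.empty((k, d, d))
    resp = resp0.copy()
    ll_hist = np.empty(max_iter)
    L = np.empty((d, d))
    logdens = np.empty((n, k))
    y = np.empty(d)

    status, floored = _m_step_core(X, resp, kind, equal, var_floor,
                                   weights, means, covs)
    if status != 0:
        return status, weights, means, covs, ll_hist[:0], False, 0, floored

    prev = -1.0e300
    converged = False
    it = 0
    while it < max_iter:
        it += 1
        # E-step: log π_k + log φ_k per observation
        for j in range(k):
            if not _cholesky_lower(covs[j], L):
                return 2, weights, means, covs, ll_hist[:it - 1], False, it, floored
            logdet = 0.0
            for a in range(d):
                logdet += 2.0 * np.log(L[a, a])
            base = np.log(weights[j]) - 0.5 * (d * _LOG_2PI + logdet)
            for i in range(n):
                for a in range(d):
                    s = X[i, a] - means[j, a]
                    for m in range(a):
                        s -= L[a, m] * y[m]
                    y[a] = s / L[a, a]
                maha = 0.0
                for a in range(d):
                    maha += y[a] * y[a]
                logdens[i, j] = base - 0.5 * maha
        ll = 0.0
        for i in range(n):
            top = logdens[i, 0]
            for j in range(1, k):
                if logdens[i, j] > top:
                    top = logdens[i, j]
            tot = 0.0
            for j in range(k):
                resp[i, j] = np.exp(logdens[i, j] - top)
                tot += resp[i, j]
            for j in range(k):
                resp[i, j] /= tot
            ll += top + np.log(tot)
        if not np.isfinite(ll):
            return 2, weights, means, covs, ll_hist[:it - 1], False, it, floored
        ll_hist[it - 1] = ll
        if ll - prev < tol * max(1.0, abs(ll)):
            converged = True
            break
        prev = ll
        status, floored = _m_step_core(X, resp, kind, equal, var_floor,
                                       weights, means, covs)
        if status != 0:
            return status, weights, means, covs, ll_hist[:it], False, it, floored
    return 0, weights, means, covs, ll_hist[:it], converged, it, floored
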