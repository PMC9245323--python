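"""Numerical core for state-dependent birth-death (SSE) likelihoods.

Along every branch the coupled ODEs for per-state extinction
probabilities E_s(t) and conditional likelihoods D_s(t) are integrated
tip-to-root with an adaptive Cash-Karp Runge-Kutta scheme:

    dE_s/dt = mu_s - (lam_s + mu_s + sum_j q_sj) E_s
              + sum_j q_sj E_j + lam_s E_s^2
    dD_s/dt = -(lam_s + mu_s + sum_j q_sj) D_s
              + sum_j q_sj D_j + 2 lam_s E_s D_s

At internal nodes daughters combine as D_s <- lam_s D_s^L D_s^R, with
per-node renormalization of D against underflow.  The state count is
generic, so the same kernel serves BiSSE (2), HiSSE (4) and CID-4 (8).
All functions are numba-compiled; the tree arrives flattened into
postorder integer arrays (see ``rangediv.sse``).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# branches of exactly zero length are integrated over this interval
# instead, to avoid degenerate steps
_MIN_BRANCH = 1e-9


@njit(cache=False)
def _deriv(y, lam, mu, Q, out):
    k = lam.size
    for i in range(k):
        qsum = 0.0
        sE = 0.0
        sD = 0.0
        for j in range(k):
            if j != i:
                qij = Q[i, j]
                if qij > 0.0:
                    qsum += qij
                    sE += qij * y[j]
                    sD += qij * y[k + j]
        s = lam[i] + mu[i] + qsum
        Ei = y[i]
        out[i] = mu[i] - s * Ei + lam[i] * Ei * Ei + sE
        out[k + i] = -s * y[k + i] + 2.0 * lam[i] * Ei * y[k + i] + sD


@njit(cache=False)
def _integrate_branch(y, T, lam, mu, Q, rtol, atol):
    """Advance (E, D) along a branch of length T, in place."""
    n = y.size
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    k5 = np.empty(n)
    k6 = np.empty(n)
    ytmp = np.empty(n)
    ynew = np.empty(n)
    t = 0.0
    h = T
    while t < T:
        if h > T - t:
            h = T - t
        _deriv(y, lam, mu, Q, k1)
        for i in range(n):
            ytmp[i] = y[i] + h * 0.2 * k1[i]
        _deriv(ytmp, lam, mu, Q, k2)
        for i in range(n):
            ytmp[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
        _deriv(ytmp, lam, mu, Q, k3)
        for i in range(n):
            ytmp[i] = y[i] + h * (
                0.3 * k1[i] - 0.9 * k2[i] + 1.2 * k3[i]
            )
        _deriv(ytmp, lam, mu, Q, k4)
        for i in range(n):
            ytmp[i] = y[i] + h * (
                -11.0 / 54.0 * k1[i]
                + 2.5 * k2[i]
                - 70.0 / 27.0 * k3[i]
                + 35.0 / 27.0 * k4[i]
            )
        _deriv(ytmp, lam, mu, Q, k5)
        for i in range(n):
            ytmp[i] = y[i] + h * (
                1631.0 / 55296.0 * k1[i]
                + 175.0 / 512.0 * k2[i]
                + 575.0 / 13824.0 * k3[i]
                + 44275.0 / 110592.0 * k4[i]
                + 253.0 / 4096.0 * k5[i]
            )
        _deriv(ytmp, lam, mu, Q, k6)
        errnorm = 0.0
        for i in range(n):
            y5 = y[i] + h * (
                37.0 / 378.0 * k1[i]
                + 250.0 / 621.0 * k3[i]
                + 125.0 / 594.0 * k4[i]
                + 512.0 / 1771.0 * k6[i]
            )
            y4 = y[i] + h * (
                2825.0 / 27648.0 * k1[i]
                + 18575.0 / 48384.0 * k3[i]
                + 13525.0 / 55296.0 * k4[i]
                + 277.0 / 14336.0 * k5[i]
                + 0.25 * k6[i]
            )
            ynew[i] = y5
            sc = atol + rtol * max(abs(y[i]), abs(y5))
            e = abs(y5 - y4) / sc
            if e > errnorm:
                errnorm = e
        if errnorm <= 1.0 or h <= 1e-14 * T:
            t += h
            for i in range(n):
                y[i] = ynew[i]
            if errnorm > 1e-30:
                fac = 0.9 * errnorm ** (-0.2)
                if fac > 5.0:
                    fac = 5.0
                h *= fac
            else:
                h *= 5.0
        else:
            fac = 0.9 * errnorm ** (-0.25)
            if fac < 0.1:
                fac = 0.1
            h *= fac
    return y


@njit(cache=False)
def sse_loglik_core(
    child_left,
    child_right,
    blen,
    tipD,
    lam,
    mu,
    Q,
    root_mode,
    root_freq,
    cond_surv,
    rtol,
    atol,
):
    """Pruning log-likelihood for a flattened bifurcating tree.

    Nodes 0..ntips-1 are tips (rows of ``tipD``); internal nodes follow in
    postorder with the root last.  ``root_mode``: 0 = weight root states
    by conditional likelihoods, 1 = flat weights, 2 = use ``root_freq``.
    """
    ntips, k = tipD.shape
    nnode = blen.size
    top = np.zeros((nnode, 2 * k))
    logsc = 0.0
    for i in range(ntips):
        y = np.zeros(2 * k)
        for s in range(k):
            y[k + s] = tipD[i, s]
        T = blen[i]
        if T <= 0.0:
            T = _MIN_BRANCH
        _integrate_branch(y, T, lam, mu, Q, rtol, atol)
        for s in range(2 * k):
            top[i, s] = y[s]
    Eroot = np.zeros(k)
    Droot = np.zeros(k)
    for idx in range(ntips, nnode):
        left = child_left[idx]
        right = child_right[idx]
        y = np.zeros(2 * k)
        mx = 0.0
        for s in range(k):
            y[s] = 0.5 * (top[left, s] + top[right, s])
            d = lam[s] * top[left, k + s] * top[right, k + s]
            y[k + s] = d
            if d > mx:
                mx = d
        if mx <= 0.0 or not np.isfinite(mx):
            return -np.inf
        for s in range(k):
            y[k + s] /= mx
        logsc += np.log(mx)
        if idx == nnode - 1:
            for s in range(k):
                Eroot[s] = y[s]
                Droot[s] = y[k + s]
        else:
            T = blen[idx]
            if T <= 0.0:
                T = _MIN_BRANCH
            _integrate_branch(y, T, lam, mu, Q, rtol, atol)
            for s in range(2 * k):
                top[idx, s] = y[s]
    sD = 0.0
    for s in range(k):
        sD += Droot[s]
    if sD <= 0.0:
        return -np.inf
    w = np.empty(k)
    if root_mode == 0:
        for s in range(k):
            w[s] = Droot[s] / sD
    elif root_mode == 1:
        for s in range(k):
            w[s] = 1.0 / k
    else:
        for s in range(k):
            w[s] = root_freq[s]
    L = 0.0
    for s in range(k):
        L += w[s] * Droot[s]
    if cond_surv:
        denom = 0.0
        for s in range(k):
            denom += w[s] * lam[s] * (1.0 - Eroot[s]) ** 2
        if denom <= 0.0:
            return -np.inf
        L /= denom
    if L <= 0.0 or not np.isfinite(L):
        return -np.inf
    return np.log(L) + logsc
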