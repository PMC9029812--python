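"""Numba kernels: weighted logistic elastic-net coordinate descent and
EM for a multivariate normal with missing data.

These are internal; the public surfaces live in :mod:`metclass.enet` and
:mod:`metclass.impute`.  The coordinate-descent solver follows the
standard penalized-IRLS scheme (quadratic approximation of the weighted
binomial log-likelihood, cyclic coordinate descent with an active set,
exact-gradient KKT scans to admit violators, warm starts along a
descending lambda path).  The EM kernel exploits the precision matrix so
each row's E-step costs O(d^2 + m^3) for m missing entries.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_PMIN = 1e-8
_ETA_CAP = 30.0


@njit(cache=False)
def _sigmoid(e):
    if e > _ETA_CAP:
        e = _ETA_CAP
    elif e < -_ETA_CAP:
        e = -_ETA_CAP
    return 1.0 / (1.0 + np.exp(-e))


@njit(cache=False)
def _soft(z, g):
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


@njit(cache=False)
def cd_logistic_path(Xt, y, v, alpha, lambdas, pf, tol, max_outer, max_inner):
    """Solve the weighted logistic elastic net along a lambda path.

    Parameters: Xt is features-by-subjects (C order), v are observation
    weights summing to one (w_i / n), pf per-feature penalty multipliers
    (0 = unpenalized).  Returns (betas [L, p], beta0s [L]).
    """
    p, n = Xt.shape
    L = lambdas.shape[0]
    betas = np.zeros((L, p))
    beta0s = np.zeros(L)

    beta = np.zeros(p)
    ybar = 0.0
    for i in range(n):
        ybar += v[i] * y[i]
    if ybar < _PMIN:
        ybar = _PMIN
    if ybar > 1.0 - _PMIN:
        ybar = 1.0 - _PMIN
    beta0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, beta0)

    active = np.zeros(p, dtype=np.bool_)
    for j in range(p):
        if pf[j] == 0.0:
            active[j] = True

    wq = np.empty(n)
    r = np.empty(n)
    den = np.empty(p)

    for l in range(L):
        lam = lambdas[l]
        while True:  # violator loop with exact KKT scans
            for outer in range(max_outer):
                # quadratic approximation at current eta
                for i in range(n):
                    pi = _sigmoid(eta[i])
                    if pi < _PMIN:
                        pi = _PMIN
                    elif pi > 1.0 - _PMIN:
                        pi = 1.0 - _PMIN
                    q = pi * (1.0 - pi)
                    wq[i] = v[i] * q
                    # working residual z - eta of the IRLS linearization
                    r[i] = (y[i] - pi) / q
                sumw = 0.0
                for i in range(n):
                    sumw += wq[i]
                for j in range(p):
                    if active[j]:
                        s = 0.0
                        for i in range(n):
                            s += wq[i] * Xt[j, i] * Xt[j, i]
                        den[j] = s
                out_delta = 0.0
                for sweep in range(max_inner):
                    dmax = 0.0
                    # intercept
                    num0 = 0.0
                    for i in range(n):
                        num0 += wq[i] * r[i]
                    d0 = num0 / sumw
                    if d0 != 0.0:
                        beta0 += d0
                        for i in range(n):
                            r[i] -= d0
                            eta[i] += d0
                        ch = sumw * d0 * d0
                        if ch > dmax:
                            dmax = ch
                    for j in range(p):
                        if not active[j]:
                            continue
                        bj = beta[j]
                        num = 0.0
                        for i in range(n):
                            num += wq[i] * Xt[j, i] * r[i]
                        num += den[j] * bj
                        bnew = _soft(num, lam * alpha * pf[j]) / (
                            den[j] + lam * (1.0 - alpha) * pf[j]
                        )
                        d = bnew - bj
                        if d != 0.0:
                            beta[j] = bnew
                            for i in range(n):
                                r[i] -= d * Xt[j, i]
                                eta[i] += d * Xt[j, i]
                            ch = den[j] * d * d
                            if ch > dmax:
                                dmax = ch
                    if dmax > out_delta:
                        out_delta = dmax
                    if dmax < tol:
                        break
                if out_delta < tol:
                    break
            # exact-gradient KKT scan over inactive features (BLAS gemv)
            resid = np.empty(n)
            for i in range(n):
                resid[i] = v[i] * (y[i] - _sigmoid(eta[i]))
            grad = np.dot(Xt, resid)
            nviol = 0
            for j in range(p):
                if active[j]:
                    continue
                if np.abs(grad[j]) > lam * alpha * pf[j] * (1.0 + 1e-9) + 1e-12:
                    active[j] = True
                    nviol += 1
            if nviol == 0:
                break
        for j in range(p):
            betas[l, j] = beta[j]
        beta0s[l] = beta0
        # features active at this lambda stay in the ever-active set for
        # warm-started continuation at the next (smaller) lambda
        for j in range(p):
            if beta[j] != 0.0 or pf[j] == 0.0:
                active[j] = True
    return betas, beta0s


@njit(cache=False)
def _chol_small(A):
    """Lower Cholesky factor of a small symmetric PD matrix (pure loops:
    avoids LAPACK call overhead for the many tiny per-row systems)."""
    m = A.shape[0]
    L = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s < 1e-12:
                    s = 1e-12
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return L


@njit(cache=False)
def _chol_solve(L, b):
    """Solve (L L') x = b by forward/back substitution."""
    m = L.shape[0]
    x = np.empty(m)
    for i in range(m):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * x[k]
        x[i] = s / L[i, i]
    for i in range(m - 1, -1, -1):
        s = x[i]
        for k in range(i + 1, m):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]
    return x


@njit(cache=False)
def _chol_inverse(L):
    """Inverse of (L L') from its Cholesky factor."""
    m = L.shape[0]
    inv = np.empty((m, m))
    e = np.zeros(m)
    for c in range(m):
        e[c] = 1.0
        col = _chol_solve(L, e)
        for r in range(m):
            inv[r, c] = col[r]
        e[c] = 0.0
    return inv


@njit(cache=False)
def _chol_ok(A):
    """True when A admits a Cholesky factorization (is numerically PD)."""
    m = A.shape[0]
    L = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 1e-12:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return True


@njit(cache=False)
def _em_sweep(X, obs, obs_f, n_miss, mu_in, sigma_in, ridge_n):
    """One EM iteration; returns (mu', sigma', observed log-lik at input)."""
    n, d = X.shape
    log2pi = np.log(2.0 * np.pi)
    lam = np.linalg.inv(sigma_in)
    cl = np.linalg.cholesky(sigma_in)
    logdet = 0.0
    for a in range(d):
        logdet += 2.0 * np.log(cl[a, a])
    U = np.empty((n, d))
    Ex = np.empty((n, d))
    for i in range(n):
        for a in range(d):
            U[i, a] = (X[i, a] - mu_in[a]) * obs_f[i, a]
            Ex[i, a] = X[i, a] * obs_f[i, a]
    T = np.dot(U, lam)
    C = np.zeros((d, d))  # accumulated conditional covariances
    ll = 0.0
    for i in range(n):
        quad_full = 0.0
        for a in range(d):
            quad_full += U[i, a] * T[i, a]
        nm = n_miss[i]
        if nm == 0:
            ll += -0.5 * (logdet + quad_full + d * log2pi)
            continue
        midx = np.empty(nm, dtype=np.int64)
        k = 0
        for a in range(d):
            if not obs[i, a]:
                midx[k] = a
                k += 1
        Lmm = np.empty((nm, nm))
        s = np.empty(nm)
        for a in range(nm):
            s[a] = T[i, midx[a]]
            for b in range(nm):
                Lmm[a, b] = lam[midx[a], midx[b]]
        clm = _chol_small(Lmm)
        cond_cov = _chol_inverse(clm)
        aa = _chol_solve(clm, s)
        quad_oo = quad_full
        for a in range(nm):
            quad_oo -= s[a] * aa[a]
        logdet_mm = 0.0
        for a in range(nm):
            logdet_mm += 2.0 * np.log(clm[a, a])
        no = d - nm
        ll += -0.5 * (logdet + logdet_mm + quad_oo + no * log2pi)
        for a in range(nm):
            Ex[i, midx[a]] = mu_in[midx[a]] - aa[a]
            for b in range(nm):
                C[midx[a], midx[b]] += cond_cov[a, b]
    ExT = np.ascontiguousarray(Ex.T)
    S2 = np.dot(ExT, Ex)
    denom = n + ridge_n
    mu = np.empty(d)
    sigma = np.empty((d, d))
    for a in range(d):
        acc = 0.0
        for i in range(n):
            acc += Ex[i, a]
        mu[a] = acc / n
    for a in range(d):
        for b in range(d):
            sigma[a, b] = (S2[a, b] + C[a, b] - n * mu[a] * mu[b]) / denom
        sigma[a, a] += ridge_n / denom
    for a in range(d):
        for b in range(a):
            m = 0.5 * (sigma[a, b] + sigma[b, a])
            sigma[a, b] = m
            sigma[b, a] = m
    return mu, sigma, ll


@njit(cache=False)
def em_mvn(X, obs, mu0, sigma0, ridge_n, tol, max_iter):
    """EM for N(mu, Sigma) with missing entries and a ridge prior.

    X is n x d with arbitrary values where ``obs`` is False; the prior
    shrinks Sigma toward the identity with weight ``ridge_n`` pseudo-
    observations (data are standardized upstream).  Iterations are
    SQUAREM-accelerated (squared extrapolation of the EM map with a
    monotonicity safeguard), which leaves the fixed point untouched but
    reaches it in far fewer sweeps; ``max_iter`` counts EM sweeps.
    Convergence is on the observed-data log-likelihood.  Returns
    (mu, sigma, ll, n_sweeps, converged).
    """
    n, d = X.shape
    obs_f = np.zeros((n, d))
    n_miss = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for a in range(d):
            if obs[i, a]:
                obs_f[i, a] = 1.0
            else:
                n_miss[i] += 1
    mu = mu0.copy()
    sigma = sigma0.copy()
    ll = -1e300
    converged = False
    sweeps = 0
    while sweeps < max_iter:
        mu1, sig1, ll0 = _em_sweep(X, obs, obs_f, n_miss, mu, sigma, ridge_n)
        mu2, sig2, ll1 = _em_sweep(X, obs, obs_f, n_miss, mu1, sig1, ridge_n)
        sweeps += 2
        if np.abs(ll1 - ll0) < tol * (1.0 + np.abs(ll1)):
            mu, sigma, ll = mu2, sig2, ll1
            converged = True
            break
        # squared extrapolation: theta' = theta0 - 2a r + a^2 v
        rr = 0.0
        vv = 0.0
        for a in range(d):
            r1 = mu1[a] - mu[a]
            v1 = mu2[a] - 2.0 * mu1[a] + mu[a]
            rr += r1 * r1
            vv += v1 * v1
            for b in range(d):
                r2 = sig1[a, b] - sigma[a, b]
                v2 = sig2[a, b] - 2.0 * sig1[a, b] + sigma[a, b]
                rr += r2 * r2
                vv += v2 * v2
        if vv <= 1e-300:
            mu, sigma, ll = mu2, sig2, ll1
            continue
        step = -np.sqrt(rr / vv)
        if step > -1.0:
            step = -1.0
        # large steps can leave the PD cone or overshoot; backtrack the
        # step toward the plain EM step (-1) until the extrapolated Sigma
        # is PD and its stabilizing sweep does not lose likelihood
        accepted = False
        mu_s = np.empty(d)
        sig_s = np.empty((d, d))
        for bt in range(8):
            for a in range(d):
                mu_s[a] = mu[a] - 2.0 * step * (mu1[a] - mu[a]) \
                    + step * step * (mu2[a] - 2.0 * mu1[a] + mu[a])
                for b in range(d):
                    sig_s[a, b] = sigma[a, b] - 2.0 * step * (
                        sig1[a, b] - sigma[a, b]) + step * step * (
                        sig2[a, b] - 2.0 * sig1[a, b] + sigma[a, b])
            if _chol_ok(sig_s):
                mu3, sig3, ll_s = _em_sweep(X, obs, obs_f, n_miss, mu_s,
                                            sig_s, ridge_n)
                sweeps += 1
                if ll_s >= ll1 - 0.01 * (1.0 + np.abs(ll1)):
                    mu, sigma, ll = mu3, sig3, ll_s
                    accepted = True
                    break
            if step >= -1.0:
                break
            step = 0.5 * (step - 1.0)
        if not accepted:
            mu, sigma, ll = mu2, sig2, ll1
    return mu, sigma, ll, sweeps, converged


@njit(cache=False)
def conditional_impute(X, obs, mu, sigma, Z, add_noise):
    """Fill missing entries with conditional draws (or means) under
    N(mu, Sigma).  Z supplies standard normals, row-aligned with X."""
    n, d = X.shape
    out = X.copy()
    lam = np.linalg.inv(sigma)
    for i in range(n):
        nm = 0
        for a in range(d):
            if not obs[i, a]:
                nm += 1
        if nm == 0:
            continue
        midx = np.empty(nm, dtype=np.int64)
        u = np.empty(d)
        k = 0
        for a in range(d):
            if not obs[i, a]:
                midx[k] = a
                k += 1
                u[a] = 0.0
            else:
                u[a] = X[i, a] - mu[a]
        t = lam @ u
        Lmm = np.empty((nm, nm))
        s = np.empty(nm)
        for a in range(nm):
            s[a] = t[midx[a]]
            for b in range(nm):
                Lmm[a, b] = lam[midx[a], midx[b]]
        clm = _chol_small(Lmm)
        aa = _chol_solve(clm, s)
        for a in range(nm):
            out[i, midx[a]] = mu[midx[a]] - aa[a]
        if add_noise:
            # if Lam_mm = L L', then solving L' u = z gives
            # cov(u) = L'^{-1} L^{-1} = Lam_mm^{-1}, the conditional cov
            u2 = np.empty(nm)
            for a in range(nm - 1, -1, -1):
                s2 = Z[i, a]
                for k in range(a + 1, nm):
                    s2 -= clm[k, a] * u2[k]
                u2[a] = s2 / clm[a, a]
            for a in range(nm):
                out[i, midx[a]] += u2[a]
    return out
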