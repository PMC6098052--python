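"""Numba kernels for the parametric-bootstrap replicate refits.

The replicate refit is the hot loop of band construction: a warm-started
4-parameter curve fit per replicate.  Uncensored replicates use a
Levenberg-Marquardt weighted least-squares step; censored replicates use an
EM iteration (impute each censored value by its truncated-normal
conditional mean at the current curve, then LM on the completed data),
which maximises the same fixed-sigma censored likelihood.
"""
import math

import numpy as np
from numba import njit

LN10 = math.log(10.0)
_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)
B_FLOOR = -30.0


@njit(cache=True)
def _mu_jac(x, t, s, mu, J):
    """Mean LRATIO curve and Jacobian wrt (u, v, w, beta) in place."""
    u, v, w, beta = x[0], x[1], x[2], x[3]
    if w > 20.0:
        w = 20.0
    alpha = math.exp(w)
    n = t.shape[0]
    has_b = v > B_FLOOR
    for j in range(n):
        ea = math.exp(min(max(u - alpha * s * t[j], -745.0), 300.0))
        if has_b:
            eb = math.exp(min(max(v - beta * s * t[j], -745.0), 300.0))
            ga = math.exp(min(max(v - alpha * s * t[j], -745.0), 300.0))
        else:
            eb = 0.0
            ga = 0.0
        tot = ea + eb + ga
        mu[j] = math.log(tot) / LN10
        inv = 1.0 / (tot * LN10)
        J[j, 0] = ea * inv
        J[j, 1] = (eb + ga) * inv
        J[j, 2] = -(alpha * s * t[j]) * (ea + ga) * inv
        J[j, 3] = -(s * t[j]) * eb * inv


@njit(cache=True)
def _lm(x, t, y, w, s, max_iter):
    """Damped Gauss-Newton (LM) for weighted least squares; warm start x
    is modified in place.  Returns the final weighted SSR."""
    n = t.shape[0]
    mu = np.empty(n)
    J = np.empty((n, 4))
    mu2 = np.empty(n)
    J2 = np.empty((n, 4))
    _mu_jac(x, t, s, mu, J)
    ssr = 0.0
    for j in range(n):
        d = mu[j] - y[j]
        ssr += w[j] * d * d
    lam = 1e-3
    g = np.empty(4)
    H = np.empty((4, 4))
    for _ in range(max_iter):
        for a in range(4):
            acc = 0.0
            for j in range(n):
                acc += w[j] * J[j, a] * (mu[j] - y[j])
            g[a] = acc
            for b in range(a, 4):
                h = 0.0
                for j in range(n):
                    h += w[j] * J[j, a] * J[j, b]
                H[a, b] = h
                H[b, a] = h
        gnorm = 0.0
        for a in range(4):
            gnorm = max(gnorm, abs(g[a]))
        if gnorm < 1e-10:
            break
        improved = False
        for _ in range(12):
            A = H.copy()
            for a in range(4):
                A[a, a] += lam * max(H[a, a], 1e-12)
            delta = np.linalg.solve(A, -g)
            xn = x + delta
            _mu_jac(xn, t, s, mu2, J2)
            ssr_n = 0.0
            for j in range(n):
                d = mu2[j] - y[j]
                ssr_n += w[j] * d * d
            if ssr_n <= ssr:
                step = 0.0
                for a in range(4):
                    step = max(step, abs(delta[a]))
                x[:] = xn
                mu[:] = mu2
                J[:] = J2
                conv = ssr - ssr_n < 1e-12 * (ssr + 1e-12) or step < 1e-9
                ssr = ssr_n
                lam = max(lam / 3.0, 1e-12)
                improved = True
                if conv:
                    return ssr
                break
            lam *= 4.0
        if not improved:
            break
    return ssr


@njit(cache=True)
def _norm_cdf(z):
    return 0.5 * math.erfc(-z / _SQRT2)


@njit(cache=True)
def _mills(z):
    """phi(z) / Phi(z), stable on the far left tail."""
    if z < -30.0:
        return -z - 1.0 / z
    c = _norm_cdf(z)
    if c <= 0.0:
        return -z - 1.0 / z
    return _INV_SQRT_2PI * math.exp(-0.5 * z * z) / c


@njit(cache=True)
def _em_tobit(x, t, y, cens_mask, w, s, lql, sig, n_em, max_iter):
    """Censored refit with sigma fixed: EM with truncated-normal imputation
    of the censored values, LM on the completed data each M-step."""
    n = t.shape[0]
    yy = y.copy()
    mu = np.empty(n)
    J = np.empty((n, 4))
    for _ in range(n_em):
        _mu_jac(x, t, s, mu, J)
        for j in range(n):
            if cens_mask[j]:
                z = (lql - mu[j]) / sig
                yy[j] = mu[j] - sig * _mills(z)
        _lm(x, t, yy, w, s, max_iter)
    return 0


@njit(cache=True)
def band_curves(x_hat, t, w, s, lql, sigma_hat, df, times, n_boot, seed,
                curves):
    """Simulate, re-censor and refit n_boot replicates; fill the curve
    matrix (n_boot x len(times)).  Deterministic given seed."""
    np.random.seed(seed)
    n = t.shape[0]
    m = times.shape[0]
    x = np.empty(4)
    mu_hat = np.empty(n)
    J = np.empty((n, 4))
    _mu_jac(x_hat, t, s, mu_hat, J)
    yb = np.empty(n)
    cmask = np.empty(n, dtype=np.bool_)
    mu_out = np.empty(m)
    J_out = np.empty((m, 4))
    for b in range(n_boot):
        if sigma_hat > 0.0:
            sig_b = sigma_hat * math.sqrt(df / np.random.chisquare(df))
        else:
            sig_b = 0.0
        any_c = False
        for j in range(n):
            yb[j] = mu_hat[j] + sig_b * np.random.normal(0.0, 1.0)
            if yb[j] < lql:
                yb[j] = lql
                cmask[j] = True
                any_c = True
            else:
                cmask[j] = False
        x[:] = x_hat
        if any_c:
            _em_tobit(x, t, yb, cmask, w, s, lql, max(sig_b, 1e-8), 8, 30)
        else:
            _lm(x, t, yb, w, s, 60)
        _mu_jac(x, times, s, mu_out, J_out)
        for k in range(m):
            curves[b, k] = mu_out[k]
    return 0
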