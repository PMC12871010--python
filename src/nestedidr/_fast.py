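"""Optional numba-accelerated kernels for the pseudo-EM inner loops.

The reference implementations live in :mod:`nestedidr.model` and
:mod:`nestedidr.baselines`; these kernels compute the same quantities (same
bracketed-Newton scheme, same tolerances) as a tight scalar loop.  If numba
is unavailable the package silently falls back to the vectorised NumPy
path.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco if not (a and callable(a[0])) else a[0]


_INV_SQRT2 = 0.7071067811865476
_INV_SQRT2PI = 0.3989422804014327


@njit(cache=True, fastmath=True)
def _mixture_inverse_kernel(u, z0, w, mu, sig, tol, ztol):  # pragma: no cover
    n = u.size
    K = w.size
    out = np.empty(n)
    for i in range(n):
        z = z0[i]
        lo = -15.0
        hi = 15.0
        for _ in range(100):
            c = 0.0
            d = 0.0
            for k in range(K):
                t = (z - mu[k]) / sig[k]
                c += w[k] * 0.5 * math.erfc(-t * _INV_SQRT2)
                d += w[k] * _INV_SQRT2PI * math.exp(-0.5 * t * t) / sig[k]
            f = c - u[i]
            if f < 0.0:
                lo = z
            elif f > 0.0:
                hi = z
            if d > 0.0:
                zn = z - f / d
            else:
                zn = 0.5 * (lo + hi)
            if not (lo < zn < hi) or not math.isfinite(zn):
                zn = 0.5 * (lo + hi)
            if abs(f) <= tol and abs(zn - z) <= ztol:
                break
            z = zn
        out[i] = z
    return out


_LOG_2PI = 1.8378770664093453


@njit(cache=True, fastmath=True)
def _equicorr_ll(s1, s2, m, mu, sig, rho):  # pragma: no cover
    """Equicorrelated normal log density from block sufficient statistics."""
    d2 = (s2 - 2.0 * mu * s1 + m * mu * mu) / (sig * sig)
    if m == 1:
        return -0.5 * (_LOG_2PI + 2.0 * math.log(sig) + d2)
    d1 = (s1 - m * mu) / sig
    c = 1.0 + (m - 1) * rho
    quad = (d2 - rho * d1 * d1 / c) / (1.0 - rho)
    logdet = 2.0 * m * math.log(sig) + (m - 1) * math.log1p(-rho) + math.log(c)
    return -0.5 * (m * _LOG_2PI + logdet + quad)


@njit(cache=True, fastmath=True)
def nested_em_pass(z, lab_start, lab_m, pi1, pi11, mu01, mu11, sig11, rho11):  # pragma: no cover
    """One fused E-step + M-step-moment pass of the nested mixture.

    Returns ``(gamma, tau1, loglik, moments, sum_gamma)`` where ``moments``
    holds per lab the weighted sums needed by the closed-form M-step:
    ``[sum w1, sum w1 zbar, sum w1 zbar^2, sum w1 within, sum w0, sum w0 zbar]``
    with ``w1 = gamma tau1``, ``w0 = gamma (1 - tau1)`` and ``within`` the
    within-candidate mean square ``sum_m (z_m - zbar)^2 / (M - 1)``.
    """
    n = z.shape[0]
    L = lab_m.size
    lp1 = math.log(pi1)
    lp0 = math.log1p(-pi1)
    lp11 = np.empty(L)
    lp01 = np.empty(L)
    for l in range(L):
        lp11[l] = math.log(pi11[l])
        lp01[l] = math.log1p(-pi11[l])
    gamma = np.empty(n)
    tau1 = np.empty((n, L))
    mom = np.zeros((L, 6))
    ll = 0.0
    sum_gamma = 0.0
    s1v = np.empty(L)
    s2v = np.empty(L)
    for i in range(n):
        log_noise = lp0
        log_signal = lp1
        for l in range(L):
            st = lab_start[l]
            m = lab_m[l]
            s1 = 0.0
            s2 = 0.0
            for j in range(st, st + m):
                v = z[i, j]
                s1 += v
                s2 += v * v
            s1v[l] = s1
            s2v[l] = s2
            lh00 = -0.5 * (m * _LOG_2PI + s2)
            a = lp01[l] + _equicorr_ll(s1, s2, m, mu01[l], 1.0, 0.0)
            b = lp11[l] + _equicorr_ll(s1, s2, m, mu11[l], sig11[l], rho11[l])
            hi = a if a > b else b
            lab_sig = hi + math.log(math.exp(a - hi) + math.exp(b - hi))
            tau1[i, l] = math.exp(b - lab_sig)
            log_noise += lh00
            log_signal += lab_sig
        hi = log_noise if log_noise > log_signal else log_signal
        lmix = hi + math.log(math.exp(log_noise - hi) + math.exp(log_signal - hi))
        g = math.exp(log_signal - lmix)
        gamma[i] = g
        ll += lmix
        sum_gamma += g
        for l in range(L):
            m = lab_m[l]
            zbar = s1v[l] / m
            w1 = g * tau1[i, l]
            w0 = g - w1
            within = (s2v[l] - m * zbar * zbar) / (m - 1) if m > 1 else 0.0
            mom[l, 0] += w1
            mom[l, 1] += w1 * zbar
            mom[l, 2] += w1 * zbar * zbar
            mom[l, 3] += w1 * within
            mom[l, 4] += w0
            mom[l, 5] += w0 * zbar
    return gamma, tau1, ll, mom, sum_gamma


@njit(cache=True, fastmath=True)
def twocomp_em_pass(z, pi1, mu, sig, rho):  # pragma: no cover
    """Fused E-step + M-step-moment pass of the two-component mixture
    (standard IDR).  Returns ``(gamma, loglik, moments)`` with the same
    moment layout as :func:`nested_em_pass` (signal weights in the first
    four slots, noise weight and mean unused)."""
    n, m = z.shape
    lp1 = math.log(pi1)
    lp0 = math.log1p(-pi1)
    gamma = np.empty(n)
    mom = np.zeros(4)
    ll = 0.0
    for i in range(n):
        s1 = 0.0
        s2 = 0.0
        for j in range(m):
            v = z[i, j]
            s1 += v
            s2 += v * v
        l0 = lp0 - 0.5 * (m * _LOG_2PI + s2)
        l1 = lp1 + _equicorr_ll(s1, s2, m, mu, sig, rho)
        hi = l0 if l0 > l1 else l1
        lmix = hi + math.log(math.exp(l0 - hi) + math.exp(l1 - hi))
        g = math.exp(l1 - lmix)
        gamma[i] = g
        ll += lmix
        zbar = s1 / m
        within = (s2 - m * zbar * zbar) / (m - 1) if m > 1 else 0.0
        mom[0] += g
        mom[1] += g * zbar
        mom[2] += g * zbar * zbar
        mom[3] += g * within
    return gamma, ll, mom


def mixture_inverse(u, z0, weights, means, sigmas, tol=1e-9, ztol=1e-9):
    """Invert a normal-mixture CDF at ``u`` (same contract as the NumPy
    safeguarded Newton, warm-started at ``z0``)."""
    u = np.ascontiguousarray(u, dtype=np.float64)
    z0 = np.ascontiguousarray(z0, dtype=np.float64)
    w = np.ascontiguousarray(weights, dtype=np.float64)
    mu = np.ascontiguousarray(means, dtype=np.float64)
    sig = np.ascontiguousarray(sigmas, dtype=np.float64)
    return _mixture_inverse_kernel(u, z0, w, mu, sig, tol, ztol)
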