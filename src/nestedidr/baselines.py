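"""Comparator methods: standard (single-level) IDR, p-value combination
meta-analysis (Fisher, Stouffer) and the rank-product statistic.

All baselines emit per-candidate scores oriented so that SMALLER = more
likely a genuine signal, matching the orientation of ``idr_between``; this
makes every method directly usable in ROC/AUC comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from . import _fast
from .estimation import ScoreMatrix, scaled_ecdf
from .model import RHO_EPS, SIGMA_EPS, _equicorr_logpdf_from_stats

__all__ = [
    "BaselineScores",
    "TwoComponentParams",
    "standard_idr",
    "ranks_to_pvalues",
    "fisher_combine",
    "stouffer_combine",
    "rank_product",
]


@dataclass
class BaselineScores:
    """Per-candidate baseline scores; smaller = more likely signal."""

    method: str
    scores: np.ndarray
    params: object = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)


@dataclass
class TwoComponentParams:
    """Parameters of the classic two-component copula mixture (standard IDR):
    noise N(0, I) versus an exchangeable signal component."""

    pi1: float
    mu: float
    sigma: float
    rho: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.pi1, self.mu, self.sigma, self.rho])


def _mix_cdf2(z, p: TwoComponentParams):
    return (1 - p.pi1) * special.ndtr(z) + p.pi1 * special.ndtr((z - p.mu) / p.sigma)


def _mix_pdf2(z, p: TwoComponentParams):
    a = np.exp(-0.5 * z**2 - 0.5 * np.log(2 * np.pi))
    t = (z - p.mu) / p.sigma
    b = np.exp(-0.5 * t**2 - 0.5 * np.log(2 * np.pi)) / p.sigma
    return (1 - p.pi1) * a + p.pi1 * b


def _mix_cdf_pdf2(z, p: TwoComponentParams):
    inv_sqrt2pi = 0.3989422804014327
    t = (z - p.mu) / p.sigma
    c = (1 - p.pi1) * special.ndtr(z) + p.pi1 * special.ndtr(t)
    d = (1 - p.pi1) * inv_sqrt2pi * np.exp(-0.5 * z * z) + (
        p.pi1 * inv_sqrt2pi / p.sigma
    ) * np.exp(-0.5 * t * t)
    return c, d


def _inverse_mix_cdf2(u, p: TwoComponentParams, x0=None, tol=1e-9, max_iter=100):
    u = np.asarray(u, dtype=float)
    lo = np.full(u.shape, -15.0)
    hi = np.full(u.shape, 15.0)
    z = special.ndtri(u) if x0 is None else np.array(x0, dtype=float)
    z = np.clip(z, -15.0 + 1e-9, 15.0 - 1e-9)
    if _fast.HAVE_NUMBA:
        return _fast.mixture_inverse(
            u,
            z,
            np.array([1.0 - p.pi1, p.pi1]),
            np.array([0.0, p.mu]),
            np.array([1.0, p.sigma]),
            tol=tol,
        )
    active = np.arange(u.size)
    for _ in range(max_iter):
        za, ua = z[active], u[active]
        cdf, pdf = _mix_cdf_pdf2(za, p)
        f = cdf - ua
        la, ha = lo[active], hi[active]
        np.copyto(la, za, where=f < 0)
        np.copyto(ha, za, where=f > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z_new = za - f / pdf
        bad = ~np.isfinite(z_new) | (z_new <= la) | (z_new >= ha)
        z_new[bad] = 0.5 * (la[bad] + ha[bad])
        pending = (np.abs(f) > tol) | (np.abs(z_new - za) > 1e-9)
        lo[active], hi[active] = la, ha
        z[active[pending]] = z_new[pending]
        active = active[pending]
        if active.size == 0:
            break
    return z


def _estep2(z: np.ndarray, p: TwoComponentParams):
    m = z.shape[1]
    s1 = z.sum(axis=1)
    s2 = np.square(z).sum(axis=1)
    l0 = _equicorr_logpdf_from_stats(s1, s2, m, 0.0, 1.0, 0.0) + np.log1p(-p.pi1)
    l1 = _equicorr_logpdf_from_stats(s1, s2, m, p.mu, p.sigma, p.rho) + np.log(p.pi1)
    lm = np.logaddexp(l0, l1)
    gamma = np.exp(l1 - lm)
    return gamma, float(lm.sum())


def _mstep2(z: np.ndarray, gamma: np.ndarray) -> TwoComponentParams:
    m = z.shape[1]
    sw = gamma.sum()
    pi1 = float(np.clip(gamma.mean(), 1e-8, 1 - 1e-8))
    zbar = z.mean(axis=1)
    mu = float((gamma * zbar).sum() / sw)
    a = float((gamma * m * np.square(zbar - mu)).sum() / sw)
    within = np.square(z - zbar[:, None]).sum(axis=1) / max(m - 1, 1)
    b = float((gamma * within).sum() / sw) if m > 1 else a
    sigma2 = (a + (m - 1) * b) / m
    rho = 1.0 - b / sigma2 if (m > 1 and sigma2 > 0) else 0.0
    return TwoComponentParams(
        pi1,
        max(mu, 1e-3),
        float(np.sqrt(max(sigma2, SIGMA_EPS**2))),
        float(np.clip(rho, RHO_EPS, 1 - RHO_EPS)),
    )


def _mstep2_from_moments(mom: np.ndarray, n: int, m: int) -> TwoComponentParams:
    """Two-component M-step from the moments of the fused numba E-step;
    same closed forms and projection as :func:`_mstep2`."""
    sw, s1z, s2z, swith = mom
    pi1 = float(np.clip(sw / n, 1e-8, 1 - 1e-8))
    mu = float(s1z / sw)
    a = m * (s2z / sw - mu * mu)
    b = float(swith / sw) if m > 1 else a
    sigma2 = (a + (m - 1) * b) / m
    rho = 1.0 - b / sigma2 if (m > 1 and sigma2 > 0) else 0.0
    return TwoComponentParams(
        pi1,
        max(mu, 1e-3),
        float(np.sqrt(max(sigma2, SIGMA_EPS**2))),
        float(np.clip(rho, RHO_EPS, 1 - RHO_EPS)),
    )


def _polish2(uniq, inv_idx, counts, p_start: TwoComponentParams, start_ll: float,
             maxfev: int = 400) -> tuple[TwoComponentParams, float]:
    """Nelder-Mead maximisation of the two-component copula log-likelihood
    from the EM solution (the pseudo-data refresh fixed point is displaced
    from the criterion's maximiser; see the nested model's polish step)."""
    from scipy import optimize

    def cll(p: TwoComponentParams) -> float:
        zu = _inverse_mix_cdf2(uniq, p)
        z = zu[inv_idx]
        if _fast.HAVE_NUMBA:
            _, ll_joint, _ = _fast.twocomp_em_pass(z, p.pi1, p.mu, p.sigma, p.rho)
        else:
            _, ll_joint = _estep2(z, p)
        return float(ll_joint) - float((counts * np.log(_mix_pdf2(zu, p))).sum())

    def neg(v: np.ndarray) -> float:
        try:
            p = TwoComponentParams(
                float(special.expit(v[0])), float(np.exp(v[1])),
                float(np.exp(v[2])), float(special.expit(v[3])),
            )
            return -cll(p)
        except (ValueError, FloatingPointError):
            return np.inf

    v0 = np.array([
        special.logit(p_start.pi1), np.log(p_start.mu),
        np.log(p_start.sigma), special.logit(p_start.rho),
    ])
    res = optimize.minimize(
        neg, v0, method="Nelder-Mead",
        options=dict(maxfev=maxfev, xatol=1e-5, fatol=1e-6),
    )
    if -res.fun <= start_ll:
        return p_start, start_ll
    v = res.x
    return (
        TwoComponentParams(
            float(special.expit(v[0])), float(np.exp(v[1])),
            float(np.exp(v[2])), float(special.expit(v[3])),
        ),
        float(-res.fun),
    )


def standard_idr(
    x: ScoreMatrix | np.ndarray,
    tol_ll: float = 1e-6,
    tol_par: float = 1e-4,
    max_outer: int = 1000,
    inits: list[TwoComponentParams] | None = None,
    polish: bool = True,
) -> BaselineScores:
    """Standard IDR: treat all columns as exchangeable replicates of one lab.

    Fits the two-component semiparametric copula mixture by the same
    pseudo-EM scheme as the nested model (rank -> scaled ECDF -> inverse
    mixture CDF; EM update; pseudo-data refresh; best-likelihood retention
    over multiple starts) and returns the posterior noise probability of
    each candidate.
    """
    xa = x.x if isinstance(x, ScoreMatrix) else np.asarray(x, dtype=float)
    n, p_cols = xa.shape
    if p_cols < 2:
        raise ValueError("standard IDR needs at least two replicate columns")
    u = np.column_stack([scaled_ecdf(xa[:, j]) for j in range(p_cols)])
    uniq, inv_idx = np.unique(u, return_inverse=True)
    inv_idx = inv_idx.reshape(u.shape)
    counts = np.bincount(inv_idx.ravel())

    if inits is None:
        inits = [
            TwoComponentParams(0.3, 2.0, 1.0, 0.8),
            TwoComponentParams(0.3, 3.0, 1.0, 0.8),
            TwoComponentParams(0.6, 2.0, 1.0, 0.5),
            TwoComponentParams(0.6, 3.0, 1.0, 0.8),
        ]

    best_ll, best_p, best_trace = -np.inf, None, None
    for p0 in inits:
        p_cur = TwoComponentParams(**vars(p0))
        warm = None
        prev_ll, trace = None, []
        par_change = np.inf
        for _ in range(max_outer):
            zu = _inverse_mix_cdf2(uniq, p_cur, x0=warm)
            warm = zu
            z = zu[inv_idx]
            if _fast.HAVE_NUMBA:
                gamma, ll_joint, mom = _fast.twocomp_em_pass(
                    z, p_cur.pi1, p_cur.mu, p_cur.sigma, p_cur.rho
                )
            else:
                gamma, ll_joint = _estep2(z, p_cur)
                mom = None
            # rank/copula likelihood (subtract the marginal Jacobian) so
            # values are comparable across iterations and starts
            ll = ll_joint - float((counts * np.log(_mix_pdf2(zu, p_cur))).sum())
            trace.append(ll)
            if ll > best_ll:
                best_ll, best_p = ll, TwoComponentParams(**vars(p_cur))
                best_trace = trace
            if prev_ll is not None:
                rel = abs(ll - prev_ll) / max(abs(prev_ll), 1.0)
                if rel < tol_ll or par_change < tol_par:
                    break
            prev_ll = ll
            if mom is not None:
                p_new = _mstep2_from_moments(mom, z.shape[0], z.shape[1])
            else:
                p_new = _mstep2(z, gamma)
            par_change = float(np.max(np.abs(p_new.as_vector() - p_cur.as_vector())))
            p_cur = p_new
    if polish:
        best_p, best_ll = _polish2(uniq, inv_idx, counts, best_p, best_ll)
    # posterior at the retained parameters
    zu = _inverse_mix_cdf2(uniq, best_p)
    gamma, _ = _estep2(zu[inv_idx], best_p)
    return BaselineScores(
        "standard_idr",
        1.0 - gamma,
        params=best_p,
        extras={"best_loglik": best_ll, "loglik_trace": np.asarray(best_trace)},
    )


def ranks_to_pvalues(x: np.ndarray) -> np.ndarray:
    """Column-wise upper-tail empirical p-values ``1 - (r - 0.5)/n``.

    Rank-only and distribution-free: under an exchangeable null every
    candidate's rank is uniform, and higher scores (higher ranks) map to
    smaller p-values.  Mid-ranks resolve ties.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    r = np.column_stack(
        [stats.rankdata(x[:, j], method="average") for j in range(x.shape[1])]
    )
    return 1.0 - (r - 0.5) / n


def fisher_combine(p: np.ndarray) -> BaselineScores:
    """Fisher's method: ``T = -2 sum log p`` against chi-square with 2P df."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        warnings.warn("zero p-values floored at 1e-300")
        p = np.maximum(p, 1e-300)
    if np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    t = -2.0 * np.log(p).sum(axis=1)
    combined = stats.chi2.sf(t, df=2 * p.shape[1])
    return BaselineScores("fisher", combined, extras={"statistic": t})


def stouffer_combine(p: np.ndarray) -> BaselineScores:
    """Stouffer's method: ``Z = sum Phi^{-1}(1-p) / sqrt(P)``."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("p-values clipped into [1e-15, 1-1e-15]")
        p = np.clip(p, 1e-15, 1 - 1e-15)
    z = special.ndtri(1.0 - p).sum(axis=1) / np.sqrt(p.shape[1])
    combined = special.ndtr(-z)  # 1 - Phi(z)
    return BaselineScores("stouffer", combined, extras={"statistic": z})


def rank_product(x: ScoreMatrix | np.ndarray) -> BaselineScores:
    """Rank product: geometric mean of descending ranks (1 = strongest).

    A candidate consistently near the top of every replicate list gets a
    small rank product; only the ordering is used downstream.
    """
    xa = x.x if isinstance(x, ScoreMatrix) else np.asarray(x, dtype=float)
    if xa.shape[1] < 2:
        raise ValueError("rank product needs at least two columns")
    n = xa.shape[0]
    # descending rank: strongest score -> rank 1, mid-ranks for ties
    desc = np.column_stack(
        [n + 1 - stats.rankdata(xa[:, j], method="average") for j in range(xa.shape[1])]
    )
    rp = np.exp(np.log(desc).mean(axis=1))
    return BaselineScores("rank_product", rp)
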