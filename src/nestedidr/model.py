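"""Core nested Gaussian copula mixture model.

The model describes scores from ``L`` independent labs, each contributing
``M_l`` replicate experiments over the same ``n`` candidates.  Each candidate
is either a genuine signal (``G=1``, prior ``pi1``) or noise (``G=0``).  A
genuine candidate is, independently per lab, either reproducible in that lab
(``K=1``, prior ``pi11``) or irreproducible (``K=0``).  On a latent scale the
lab-``l`` replicate vector of a candidate is multivariate normal with an
equicorrelated (exchangeable) covariance

    Sigma = sigma^2 [ (1 - rho) I + rho J ],

whose mean/scale/correlation depend on the latent state ``(G, K)``:

    (0,0)  noise:                    mu = 0,     sigma = 1,        rho = 0
    (1,0)  genuine, irreproducible:  mu = mu01,  sigma = 1,        rho = 0
    (1,1)  genuine, reproducible:    mu = mu11,  sigma = sigma11,  rho = rho11

The observed scores are arbitrary monotone transforms of the latent values,
so only ranks carry information; estimation works on pseudo-data obtained by
mapping scaled empirical CDF values through the inverse of the latent
marginal mixture CDF ``U``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from . import _fast

__all__ = [
    "StudyDesign",
    "ModelParams",
    "component_log_density",
    "marginal_mixture_cdf",
    "marginal_mixture_pdf",
    "inverse_marginal_cdf",
    "log_likelihood",
]

#: numerical margin keeping correlations strictly inside the valid region
RHO_EPS = 1e-4
#: minimal separation enforced between 0 < mu01 < mu11
MU_EPS = 1e-3
#: floor for standard deviations
SIGMA_EPS = 1e-3

_LOG_2PI = float(np.log(2.0 * np.pi))


def _norm_cdf(x):
    return special.ndtr(x)


def _norm_logpdf(x):
    return -0.5 * (_LOG_2PI + np.square(x))


@dataclass(frozen=True)
class StudyDesign:
    """Layout of a multi-lab study: which score columns belong to which lab.

    Parameters
    ----------
    M : sequence of int
        Number of replicates contributed by each lab; ``len(M)`` is the
        number of labs ``L``.  Columns of a score matrix are assumed to be
        grouped by lab in this order.
    column_names : sequence of str, optional
        One identifier per replicate column; generated as ``lab{l}_rep{m}``
        when omitted.
    """

    M: tuple[int, ...]
    column_names: tuple[str, ...] = field(default=None)

    def __post_init__(self):
        M = tuple(int(m) for m in self.M)
        if len(M) < 1:
            raise ValueError("at least one lab is required")
        if any(m < 1 for m in M):
            raise ValueError("every lab needs at least one replicate")
        object.__setattr__(self, "M", M)
        if self.column_names is None:
            names = tuple(
                f"lab{l + 1}_rep{m + 1}" for l, ml in enumerate(M) for m in range(ml)
            )
            object.__setattr__(self, "column_names", names)
        else:
            names = tuple(str(c) for c in self.column_names)
            if len(names) != sum(M):
                raise ValueError("column_names length must equal total replicates")
            object.__setattr__(self, "column_names", names)

    @property
    def L(self) -> int:
        return len(self.M)

    @property
    def P(self) -> int:
        return sum(self.M)

    @property
    def lab_slices(self) -> list[slice]:
        """Column slice of each lab in the grouped score matrix."""
        out, start = [], 0
        for m in self.M:
            out.append(slice(start, start + m))
            start += m
        return out

    def lab_of_column(self, j: int) -> int:
        for l, s in enumerate(self.lab_slices):
            if s.start <= j < s.stop:
                return l
        raise IndexError(j)


@dataclass
class ModelParams:
    """Free parameters of the nested mixture.

    ``pi1`` is the global proportion of genuine signals; the remaining
    entries are per-lab arrays of length ``L``.  The noise and
    genuine-irreproducible components have fixed unit variance, zero
    correlation and (for noise) zero mean — these are identifiability
    constants, not free parameters.
    """

    pi1: float
    pi11: np.ndarray
    mu01: np.ndarray
    mu11: np.ndarray
    sigma11: np.ndarray
    rho11: np.ndarray

    def __post_init__(self):
        self.pi11 = np.atleast_1d(np.asarray(self.pi11, dtype=float))
        self.mu01 = np.atleast_1d(np.asarray(self.mu01, dtype=float))
        self.mu11 = np.atleast_1d(np.asarray(self.mu11, dtype=float))
        self.sigma11 = np.atleast_1d(np.asarray(self.sigma11, dtype=float))
        self.rho11 = np.atleast_1d(np.asarray(self.rho11, dtype=float))
        self.pi1 = float(self.pi1)

    @property
    def L(self) -> int:
        return self.pi11.shape[0]

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1

    def validate(self) -> None:
        if not (0.0 < self.pi1 < 1.0):
            raise ValueError(f"pi1 must lie in (0,1), got {self.pi1}")
        lengths = {a.shape[0] for a in (self.pi11, self.mu01, self.mu11, self.sigma11, self.rho11)}
        if len(lengths) != 1:
            raise ValueError("per-lab parameter arrays must share one length")
        if np.any((self.pi11 <= 0) | (self.pi11 >= 1)):
            raise ValueError("pi11 must lie strictly in (0,1)")
        if np.any(self.mu01 <= 0) or np.any(self.mu11 <= self.mu01):
            raise ValueError("require mu11 > mu01 > 0")
        if np.any(self.sigma11 <= 0):
            raise ValueError("sigma11 must be positive")
        if np.any((self.rho11 < RHO_EPS) | (self.rho11 > 1 - RHO_EPS)):
            raise ValueError(f"rho11 must lie in [{RHO_EPS}, {1 - RHO_EPS}]")

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.pi1,
            self.pi11.copy(),
            self.mu01.copy(),
            self.mu11.copy(),
            self.sigma11.copy(),
            self.rho11.copy(),
        )

    def as_vector(self) -> np.ndarray:
        """Flat view used for convergence checks and reporting."""
        return np.concatenate(
            [[self.pi1], self.pi11, self.mu01, self.mu11, self.sigma11, self.rho11]
        )

    def component(self, g: int, k: int, lab: int) -> tuple[float, float, float]:
        """(mu, sigma, rho) of the ``(g, k)`` component in ``lab``."""
        if (g, k) == (0, 0):
            return 0.0, 1.0, 0.0
        if (g, k) == (1, 0):
            return float(self.mu01[lab]), 1.0, 0.0
        if (g, k) == (1, 1):
            return (
                float(self.mu11[lab]),
                float(self.sigma11[lab]),
                float(self.rho11[lab]),
            )
        raise ValueError("noise has no reproducible sub-state: (g,k)=(0,1) is invalid")


def equicorrelated_logpdf(z, mu: float, sigma: float, rho: float) -> np.ndarray:
    """Log density of N(mu*1, sigma^2[(1-rho)I + rho J]) evaluated row-wise.

    Uses the closed-form determinant ``sigma^{2M}(1-rho)^{M-1}(1+(M-1)rho)``
    and the matching quadratic-form identity instead of a generic solve;
    exact for the exchangeable covariance and valid for
    ``-1/(M-1) < rho < 1``.

    Parameters
    ----------
    z : array, shape (..., M)
        Latent replicate vectors; the last axis runs over replicates.
    """
    z = np.asarray(z, dtype=float)
    m = z.shape[-1]
    if not (-1.0 / max(m - 1, 1) < rho < 1.0):
        raise ValueError(f"rho={rho} outside the positive-definite range for M={m}")
    d = (z - mu) / sigma
    s1 = d.sum(axis=-1)
    s2 = np.square(d).sum(axis=-1)
    c = 1.0 + (m - 1) * rho
    if m == 1:
        quad = s2
        logdet = 2.0 * np.log(sigma)
    else:
        quad = (s2 - rho * np.square(s1) / c) / (1.0 - rho)
        logdet = 2.0 * m * np.log(sigma) + (m - 1) * np.log1p(-rho) + np.log(c)
    return -0.5 * (m * _LOG_2PI + logdet + quad)


def component_log_density(z_lab, g: int, k: int, params: ModelParams, lab: int) -> np.ndarray:
    """Log density of a lab's replicate vector under latent state ``(g, k)``."""
    mu, sigma, rho = params.component(g, k, lab)
    return equicorrelated_logpdf(z_lab, mu, sigma, rho)


def marginal_mixture_cdf(z, params: ModelParams, lab: int) -> np.ndarray:
    """Marginal CDF ``U`` of a single latent replicate value in ``lab``.

    U(z) = pi0 Phi(z) + pi1 [ pi01 Phi(z - mu01) + pi11 Phi((z - mu11)/sigma11) ]
    """
    z = np.asarray(z, dtype=float)
    pi11 = params.pi11[lab]
    u = params.pi0 * _norm_cdf(z) + params.pi1 * (
        (1.0 - pi11) * _norm_cdf(z - params.mu01[lab])
        + pi11 * _norm_cdf((z - params.mu11[lab]) / params.sigma11[lab])
    )
    return u


def marginal_mixture_pdf(z, params: ModelParams, lab: int) -> np.ndarray:
    """Density of the marginal mixture ``U'``; used by the Newton inverse."""
    z = np.asarray(z, dtype=float)
    pi11 = params.pi11[lab]
    s = params.sigma11[lab]
    return params.pi0 * np.exp(_norm_logpdf(z)) + params.pi1 * (
        (1.0 - pi11) * np.exp(_norm_logpdf(z - params.mu01[lab]))
        + pi11 * np.exp(_norm_logpdf((z - params.mu11[lab]) / s)) / s
    )


def _mixture_cdf_and_pdf(z, params: ModelParams, lab: int):
    """Marginal mixture CDF and density in one pass (Newton inner loop)."""
    pi11 = params.pi11[lab]
    pi01 = 1.0 - pi11
    s = params.sigma11[lab]
    t0 = z
    t1 = z - params.mu01[lab]
    t2 = (z - params.mu11[lab]) / s
    c0, c1, c2 = special.ndtr(t0), special.ndtr(t1), special.ndtr(t2)
    inv_sqrt2pi = 0.3989422804014327
    p0 = inv_sqrt2pi * np.exp(-0.5 * np.square(t0))
    p1 = inv_sqrt2pi * np.exp(-0.5 * np.square(t1))
    p2 = inv_sqrt2pi * np.exp(-0.5 * np.square(t2)) / s
    pi0, pi1 = params.pi0, params.pi1
    cdf = pi0 * c0 + pi1 * (pi01 * c1 + pi11 * c2)
    pdf = pi0 * p0 + pi1 * (pi01 * p1 + pi11 * p2)
    return cdf, pdf


def inverse_marginal_cdf(
    u,
    params: ModelParams,
    lab: int,
    *,
    x0=None,
    tol: float = 1e-9,
    max_iter: int = 100,
    bracket: tuple[float, float] = (-15.0, 15.0),
) -> np.ndarray:
    """Invert the marginal mixture CDF by safeguarded Newton iteration.

    Newton steps use the closed-form mixture density and fall back to
    bisection whenever a step leaves the current bracket, so convergence is
    guaranteed on ``bracket``.  ``x0`` supplies optional warm starts (e.g.
    the previous pseudo-data iterate).
    """
    u = np.asarray(u, dtype=float)
    scalar = u.ndim == 0
    shape = u.shape
    u = np.atleast_1d(u).ravel()
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("u must lie strictly in (0,1)")
    lo = np.full(u.shape, bracket[0])
    hi = np.full(u.shape, bracket[1])
    if x0 is None:
        # standard-normal quantile: within O(1) of the mixture quantile
        z = np.clip(special.ndtri(u), bracket[0] + 1e-9, bracket[1] - 1e-9)
    else:
        z = np.clip(np.array(x0, dtype=float).ravel(), bracket[0] + 1e-9, bracket[1] - 1e-9)
    if _fast.HAVE_NUMBA and bracket == (-15.0, 15.0):
        pi11 = params.pi11[lab]
        z = _fast.mixture_inverse(
            u,
            z,
            np.array([params.pi0, params.pi1 * (1.0 - pi11), params.pi1 * pi11]),
            np.array([0.0, params.mu01[lab], params.mu11[lab]]),
            np.array([1.0, 1.0, params.sigma11[lab]]),
            tol=tol,
        )
        return z[0] if scalar else z.reshape(shape)
    # active-set Newton: only re-evaluate points that have not converged
    active = np.arange(u.size)
    for _ in range(max_iter):
        za, ua = z[active], u[active]
        cdf, pdf = _mixture_cdf_and_pdf(za, params, lab)
        f = cdf - ua
        la, ha = lo[active], hi[active]
        np.copyto(la, za, where=f < 0)
        np.copyto(ha, za, where=f > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z_new = za - f / pdf
        bad = ~np.isfinite(z_new) | (z_new <= la) | (z_new >= ha)
        z_new[bad] = 0.5 * (la[bad] + ha[bad])
        # converged only when the CDF residual AND the z-step are tiny:
        # in the tails the CDF is flat, so the residual alone cannot pin z
        pending = (np.abs(f) > tol) | (np.abs(z_new - za) > 1e-9)
        lo[active], hi[active] = la, ha
        z[active[pending]] = z_new[pending]
        active = active[pending]
        if active.size == 0:
            break
    else:
        f = marginal_mixture_cdf(z, params, lab) - u
        if np.any(np.abs(f) > 1e-6):
            raise RuntimeError("inverse CDF did not converge within the bracket")
    return z[0] if scalar else z.reshape(shape)


def _equicorr_logpdf_from_stats(
    s1: np.ndarray, s2: np.ndarray, m: int, mu: float, sigma: float, rho: float
) -> np.ndarray:
    """Equicorrelated log density from the sufficient statistics
    ``s1 = sum_m z_m`` and ``s2 = sum_m z_m^2`` (one pass over the block
    serves all mixture components)."""
    d2 = (s2 - 2.0 * mu * s1 + m * mu * mu) / (sigma * sigma)
    d1 = (s1 - m * mu) / sigma
    if m == 1:
        return -0.5 * (_LOG_2PI + 2.0 * np.log(sigma) + d2)
    c = 1.0 + (m - 1) * rho
    quad = (d2 - rho * np.square(d1) / c) / (1.0 - rho)
    logdet = 2.0 * m * np.log(sigma) + (m - 1) * np.log1p(-rho) + np.log(c)
    return -0.5 * (m * _LOG_2PI + logdet + quad)


def lab_state_log_densities(
    z: np.ndarray, params: ModelParams, design: StudyDesign
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-candidate log component densities for every lab.

    Returns arrays of shape ``(n, L)``: ``log h00``, ``log h01`` and
    ``log h11`` of each lab's replicate block.  Shared workhorse of the
    likelihood, the E-step and the posterior scores.
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    L = design.L
    lh00 = np.empty((n, L))
    lh01 = np.empty((n, L))
    lh11 = np.empty((n, L))
    for l, sl in enumerate(design.lab_slices):
        block = z[:, sl]
        m = block.shape[1]
        s1 = block.sum(axis=1)
        s2 = np.square(block).sum(axis=1)
        lh00[:, l] = _equicorr_logpdf_from_stats(s1, s2, m, 0.0, 1.0, 0.0)
        lh01[:, l] = _equicorr_logpdf_from_stats(
            s1, s2, m, float(params.mu01[l]), 1.0, 0.0
        )
        lh11[:, l] = _equicorr_logpdf_from_stats(
            s1,
            s2,
            m,
            float(params.mu11[l]),
            float(params.sigma11[l]),
            float(params.rho11[l]),
        )
    return lh00, lh01, lh11


def candidate_log_mixture(
    z: np.ndarray, params: ModelParams, design: StudyDesign
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log of the noise term, signal term, and their mixture, per candidate.

    noise term : log[ pi0 * prod_l h00 ]
    signal term: log[ pi1 * prod_l (pi01 h01 + pi11 h11) ]
    """
    lh00, lh01, lh11 = lab_state_log_densities(z, params, design)
    lp11 = np.log(params.pi11)
    lp01 = np.log1p(-params.pi11)
    lab_signal = np.logaddexp(lp01 + lh01, lp11 + lh11)  # (n, L)
    log_noise = np.log(params.pi0) + lh00.sum(axis=1)
    log_signal = np.log(params.pi1) + lab_signal.sum(axis=1)
    return log_noise, log_signal, np.logaddexp(log_noise, log_signal)


def log_likelihood(z: np.ndarray, params: ModelParams, design: StudyDesign) -> float:
    """Observed-data log likelihood of the pseudo-data under ``params``.

    Marginalises the latent ``(G, K)`` states analytically:

        sum_i log[ pi0 prod_l h00 + pi1 prod_l (pi01 h01 + pi11 h11) ]

    evaluated entirely in log space.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        bad = int(np.argwhere(~np.isfinite(z).all(axis=1))[0, 0])
        raise ValueError(f"non-finite pseudo-data at candidate index {bad}")
    _, _, log_mix = candidate_log_mixture(z, params, design)
    if not np.all(np.isfinite(log_mix)):
        bad = int(np.argwhere(~np.isfinite(log_mix))[0, 0])
        raise FloatingPointError(f"non-finite likelihood term at candidate index {bad}")
    return float(log_mix.sum())


def copula_log_likelihood(z: np.ndarray, params: ModelParams, design: StudyDesign) -> float:
    """Rank (copula) log-likelihood: the joint log density minus the marginal
    mixture log density of every pseudo-datum.

    For pseudo-data ``z = U^{-1}(u)`` with the same ``u`` grid, this is the
    log copula density of the model at ``u`` and is the quantity that can be
    compared across parameter values: the marginal Jacobian it subtracts is
    exactly what changes when the latent scale is re-parametrised, so scale
    drift cannot inflate it.  Within one fixed pseudo-data set it differs
    from :func:`log_likelihood` only through the ``theta``-dependent
    Jacobian term.
    """
    ll = log_likelihood(z, params, design)
    jac = 0.0
    for l, sl in enumerate(design.lab_slices):
        jac += float(np.log(marginal_mixture_pdf(z[:, sl], params, l)).sum())
    return ll - jac
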