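"""Pseudo-EM estimation of the nested copula mixture from ranked scores.

The algorithm alternates two steps until convergence:

1. construct pseudo-data on the latent scale by mapping each column's scaled
   empirical CDF ``r/(n+1)`` through the inverse marginal mixture CDF of its
   lab, evaluated at the current parameters;
2. run an EM update of the parameters on the fixed pseudo-data.

The pseudo-data refresh is not guaranteed to increase the likelihood, so the
iterate with the highest observed likelihood across all outer iterations and
all starts is retained as the estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from . import _fast
from .model import (
    MU_EPS,
    RHO_EPS,
    SIGMA_EPS,
    ModelParams,
    StudyDesign,
    copula_log_likelihood,
    inverse_marginal_cdf,
    lab_state_log_densities,
    marginal_mixture_pdf,
)

__all__ = [
    "ScoreMatrix",
    "FitControls",
    "FitResult",
    "scaled_ecdf",
    "make_pseudo_data",
    "e_step",
    "m_step",
    "fit",
    "default_initializations",
]


@dataclass
class ScoreMatrix:
    """Observed score matrix: one row per candidate, one column per replicate.

    Only ranks of each column are used downstream; scales may differ
    arbitrarily between columns.  Higher score = stronger evidence.
    """

    x: np.ndarray
    design: StudyDesign
    candidate_ids: np.ndarray = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("score matrix must be two-dimensional")
        n, p = self.x.shape
        if p != self.design.P:
            raise ValueError(f"matrix has {p} columns but design expects {self.design.P}")
        if n < p + 2:
            raise ValueError(f"need at least P+2={p + 2} candidates, got {n}")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("score matrix contains missing or non-finite values")
        for j in range(p):
            if np.unique(self.x[:, j]).size < 3:
                raise ValueError(
                    f"column {self.design.column_names[j]!r} has fewer than 3 distinct values"
                )
        if self.candidate_ids is None:
            self.candidate_ids = np.array([f"cand_{i}" for i in range(n)])
        else:
            self.candidate_ids = np.asarray(self.candidate_ids)
            if self.candidate_ids.shape[0] != n:
                raise ValueError("candidate_ids length must match number of rows")

    @property
    def n(self) -> int:
        return self.x.shape[0]


@dataclass
class FitControls:
    """Convergence and robustness knobs of the pseudo-EM fit."""

    tol_ll: float = 1e-6  # relative log-likelihood change
    tol_par: float = 1e-4  # max absolute parameter change
    max_outer: int = 1000
    #: freeze pi11 at this value (two-component reduction); None = free
    freeze_pi11: float | None = None
    #: component starvation threshold on the total responsibility mass
    min_weight: float = 1e-6
    #: direct maximisation of the copula log-likelihood after the EM loop;
    #: the refresh fixed point is not the criterion's maximiser (the pass is
    #: not an ascent step once the pseudo-data move with the parameters)
    polish: bool = True
    polish_maxfev: int = 600


@dataclass
class FitResult:
    params: ModelParams
    loglik_trace: np.ndarray
    best_loglik: float
    n_outer_iters: int
    converged: bool
    init_label: str = ""
    all_starts: list = field(default_factory=list)

    def __post_init__(self):
        self.loglik_trace = np.asarray(self.loglik_trace, dtype=float)


def scaled_ecdf(column: np.ndarray) -> np.ndarray:
    """Scaled empirical CDF ``r_i/(n+1)`` with mid-ranks for ties.

    The ``n/(n+1)`` scaling keeps the values strictly inside (0,1) so the
    inverse normal/mixture transform stays finite at the extremes.
    """
    column = np.asarray(column, dtype=float)
    n = column.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    if np.unique(column).size == 1:
        raise ValueError("constant column: ranks carry no information")
    return stats.rankdata(column, method="average") / (n + 1.0)


class PseudoDataTransformer:
    """Caches the rank structure of a score matrix for fast repeated
    pseudo-data construction during the outer pseudo-EM loop.

    Ranks never change across iterations, so each refresh only has to invert
    ``U`` at the (sorted, unique) scaled-ECDF values of each lab, warm-started
    from the previous iterate.
    """

    def __init__(self, x: ScoreMatrix):
        self.design = x.design
        n, p = x.x.shape
        u = np.column_stack([scaled_ecdf(x.x[:, j]) for j in range(p)])
        self._lab_unique: list[np.ndarray] = []
        self._lab_index: list[np.ndarray] = []
        self._warm: list[np.ndarray | None] = []
        self._lab_counts: list[np.ndarray] = []
        for sl in self.design.lab_slices:
            block = u[:, sl]
            uniq, idx = np.unique(block, return_inverse=True)
            idx = idx.reshape(block.shape)
            self._lab_unique.append(uniq)
            self._lab_index.append(idx)
            self._lab_counts.append(np.bincount(idx.ravel()))
            self._warm.append(None)
        self.n = n

    def transform(self, params: ModelParams) -> np.ndarray:
        z = np.empty((self.n, self.design.P))
        for l, sl in enumerate(self.design.lab_slices):
            zu = inverse_marginal_cdf(
                self._lab_unique[l], params, l, x0=self._warm[l]
            )
            self._warm[l] = zu
            z[:, sl] = zu[self._lab_index[l]]
        return z

    def log_jacobian(self, params: ModelParams) -> float:
        """Sum of log marginal mixture densities at the last transform's
        pseudo-data (computed on unique values with multiplicities)."""
        total = 0.0
        for l in range(self.design.L):
            pdf = marginal_mixture_pdf(self._warm[l], params, l)
            total += float((self._lab_counts[l] * np.log(pdf)).sum())
        return total


def make_pseudo_data(x: ScoreMatrix, params: ModelParams) -> np.ndarray:
    """Latent-scale pseudo-data ``U^{-1}(r/(n+1))`` for every column."""
    return PseudoDataTransformer(x).transform(params)


def e_step(
    z: np.ndarray, params: ModelParams, design: StudyDesign
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior responsibilities of the latent states.

    Returns
    -------
    gamma : (n,) array
        ``P(G_i = 1 | z_i)`` using all labs' data.
    tau1 : (n, L) array
        ``P(K_i^{(l)} = 1 | G_i = 1, z_i^{(l)})`` from lab ``l``'s data only
        (labs are conditionally independent given ``G``).
    loglik : float
        Observed log-likelihood of ``z`` under ``params`` (free by-product).
    """
    lh00, lh01, lh11 = lab_state_log_densities(z, params, design)
    lp11 = np.log(params.pi11)
    lp01 = np.log1p(-params.pi11)
    a = lp01 + lh01
    b = lp11 + lh11
    lab_signal = np.logaddexp(a, b)
    tau1 = np.exp(b - lab_signal)
    log_noise = np.log(params.pi0) + lh00.sum(axis=1)
    log_signal = np.log(params.pi1) + lab_signal.sum(axis=1)
    log_mix = np.logaddexp(log_noise, log_signal)
    gamma = np.exp(log_signal - log_mix)
    return gamma, tau1, float(log_mix.sum())


def _equicorrelated_weighted_mle(
    block: np.ndarray, w: np.ndarray
) -> tuple[float, float, float]:
    """Weighted MLE of (mu, sigma^2, rho) for the exchangeable normal family.

    With row means ``zbar`` and weights ``w``, let ``a`` be the weighted mean
    of ``M (zbar - mu)^2`` (between-replicate variance scale) and ``b`` the
    weighted mean of ``sum_m (z_m - zbar)^2 / (M-1)`` (within-candidate mean
    square).  Then ``sigma^2 = (a + (M-1) b)/M`` and ``rho = 1 - b/sigma^2``.
    """
    m = block.shape[1]
    sw = w.sum()
    zbar = block.mean(axis=1)
    mu = float((w * zbar).sum() / sw)
    a = float((w * m * np.square(zbar - mu)).sum() / sw)
    if m == 1:
        return mu, a, 0.0
    within = np.square(block - zbar[:, None]).sum(axis=1) / (m - 1)
    b = float((w * within).sum() / sw)
    sigma2 = (a + (m - 1) * b) / m
    rho = 1.0 - b / sigma2 if sigma2 > 0 else 0.0
    return mu, sigma2, rho


def m_step(
    z: np.ndarray,
    responsibilities: tuple[np.ndarray, np.ndarray],
    design: StudyDesign,
    prev: ModelParams,
    controls: FitControls | None = None,
) -> ModelParams:
    """Closed-form weighted-MLE parameter update with constraint projection.

    Components whose total responsibility mass falls below
    ``controls.min_weight`` are starved: their parameters are carried over
    from ``prev`` and a warning is issued.
    """
    controls = controls or FitControls()
    gamma, tau1 = responsibilities
    n = z.shape[0]
    new = prev.copy()

    new.pi1 = float(np.clip(gamma.mean(), 1e-8, 1 - 1e-8))
    sg = gamma.sum()
    for l, sl in enumerate(design.lab_slices):
        block = z[:, sl]
        w1 = gamma * tau1[:, l]
        w0 = gamma * (1.0 - tau1[:, l])
        if controls.freeze_pi11 is None:
            new.pi11[l] = np.clip(w1.sum() / sg, 1e-8, 1 - 1e-8)
        else:
            new.pi11[l] = controls.freeze_pi11
        # irreproducible-signal component: unit variance, free mean
        if controls.freeze_pi11 is None:
            if w0.sum() < controls.min_weight:
                warnings.warn(
                    f"lab {l + 1}: irreproducible component starved; keeping previous mean"
                )
            else:
                new.mu01[l] = (w0[:, None] * block).sum() / (w0.sum() * block.shape[1])
        # reproducible component: full equicorrelated MLE
        if w1.sum() < controls.min_weight:
            warnings.warn(
                f"lab {l + 1}: reproducible component starved; keeping previous parameters"
            )
        else:
            mu, sigma2, rho = _equicorrelated_weighted_mle(block, w1)
            new.mu11[l] = mu
            new.sigma11[l] = np.sqrt(max(sigma2, SIGMA_EPS**2))
            new.rho11[l] = rho
    # projection onto the identifiability constraints
    new.sigma11 = np.maximum(new.sigma11, SIGMA_EPS)
    new.rho11 = np.clip(new.rho11, RHO_EPS, 1 - RHO_EPS)
    new.mu11 = np.maximum(new.mu11, 2 * MU_EPS)
    new.mu01 = np.clip(new.mu01, MU_EPS, new.mu11 - MU_EPS)
    return new


def _m_step_from_moments(
    mom: np.ndarray,
    sum_gamma: float,
    n: int,
    design: StudyDesign,
    prev: ModelParams,
    controls: FitControls,
) -> ModelParams:
    """M-step update from the weighted moments accumulated by the fused
    numba E-step pass; same closed forms and projection as :func:`m_step`."""
    new = prev.copy()
    new.pi1 = float(np.clip(sum_gamma / n, 1e-8, 1 - 1e-8))
    for l in range(design.L):
        sw1, s1z, s2z, swith, sw0, s0z = mom[l]
        m = design.M[l]
        if controls.freeze_pi11 is None:
            new.pi11[l] = np.clip(sw1 / sum_gamma, 1e-8, 1 - 1e-8)
            if sw0 < controls.min_weight:
                warnings.warn(
                    f"lab {l + 1}: irreproducible component starved; keeping previous mean"
                )
            else:
                new.mu01[l] = s0z / sw0
        else:
            new.pi11[l] = controls.freeze_pi11
        if sw1 < controls.min_weight:
            warnings.warn(
                f"lab {l + 1}: reproducible component starved; keeping previous parameters"
            )
        else:
            mu = s1z / sw1
            a = m * (s2z / sw1 - mu * mu)
            if m == 1:
                sigma2, rho = a, 0.0
            else:
                b = swith / sw1
                sigma2 = (a + (m - 1) * b) / m
                rho = 1.0 - b / sigma2 if sigma2 > 0 else 0.0
            new.mu11[l] = mu
            new.sigma11[l] = np.sqrt(max(sigma2, SIGMA_EPS**2))
            new.rho11[l] = rho
    new.sigma11 = np.maximum(new.sigma11, SIGMA_EPS)
    new.rho11 = np.clip(new.rho11, RHO_EPS, 1 - RHO_EPS)
    new.mu11 = np.maximum(new.mu11, 2 * MU_EPS)
    new.mu01 = np.clip(new.mu01, MU_EPS, new.mu11 - MU_EPS)
    return new


def _moment_start(x: ScoreMatrix) -> ModelParams:
    """Data-driven initialization from normal scores of the ranks.

    Uses the separation between the upper quartile and the rest of each
    lab's normal scores for the signal mean, and the pairwise correlation of
    upper-quartile rows for the reproducible correlation.
    """
    design = x.design
    z0 = np.column_stack(
        [special.ndtri(scaled_ecdf(x.x[:, j])) for j in range(design.P)]
    )
    L = design.L
    mu11 = np.empty(L)
    rho11 = np.empty(L)
    for l, sl in enumerate(design.lab_slices):
        block = z0[:, sl]
        zbar = block.mean(axis=1)
        hi = zbar >= np.quantile(zbar, 0.75)
        mu11[l] = np.clip(block[hi].mean() - block[~hi].mean(), 1.0, 5.0)
        if block.shape[1] >= 2:
            c = np.corrcoef(block[hi].T)
            rho = np.mean(c[np.triu_indices_from(c, k=1)])
        else:
            rho = 0.5
        rho11[l] = np.clip(rho, 0.2, 0.95)
    return ModelParams(
        pi1=0.5,
        pi11=np.full(L, 0.7),
        mu01=np.clip(0.4 * mu11, MU_EPS, None),
        mu11=mu11,
        sigma11=np.ones(L),
        rho11=rho11,
    )


def default_initializations(x: ScoreMatrix) -> list[tuple[str, ModelParams]]:
    """One moment-based start plus three spread-out presets."""
    L = x.design.L
    starts = [("moment", _moment_start(x))]
    for label, (pi1, mu) in (
        ("preset_lo", (0.3, 2.0)),
        ("preset_mid", (0.3, 3.0)),
        ("preset_hi", (0.6, 3.0)),
    ):
        starts.append(
            (
                label,
                ModelParams(
                    pi1=pi1,
                    pi11=np.full(L, 0.75),
                    mu01=np.full(L, 1.0),
                    mu11=np.full(L, mu),
                    sigma11=np.ones(L),
                    rho11=np.full(L, 0.8),
                ),
            )
        )
    return starts


def _fit_single(
    transformer: PseudoDataTransformer,
    init: ModelParams,
    design: StudyDesign,
    controls: FitControls,
) -> tuple[ModelParams, np.ndarray, float, int, bool]:
    theta = init.copy()
    if controls.freeze_pi11 is not None:
        theta.pi11[:] = controls.freeze_pi11
    trace = []
    best_ll = -np.inf
    best_theta = theta
    prev_ll = None
    converged = False
    par_change = np.inf
    use_fast = _fast.HAVE_NUMBA
    lab_start = np.array([sl.start for sl in design.lab_slices], dtype=np.int64)
    lab_m = np.array(design.M, dtype=np.int64)
    for it in range(controls.max_outer):
        z = transformer.transform(theta)
        if use_fast:
            gamma, tau1, ll_joint, mom, sum_gamma = _fast.nested_em_pass(
                z,
                lab_start,
                lab_m,
                theta.pi1,
                theta.pi11,
                theta.mu01,
                theta.mu11,
                theta.sigma11,
                theta.rho11,
            )
        else:
            gamma, tau1, ll_joint = e_step(z, theta, design)
        # rank/copula likelihood: comparable across iterations and starts,
        # unlike the joint latent-scale density (whose Jacobian varies with
        # the current parameters' marginal transform)
        ll = ll_joint - transformer.log_jacobian(theta)
        trace.append(ll)
        if ll > best_ll:
            best_ll, best_theta = ll, theta.copy()
        if prev_ll is not None:
            rel = abs(ll - prev_ll) / max(abs(prev_ll), 1.0)
            if rel < controls.tol_ll or par_change < controls.tol_par:
                converged = True
                break
        prev_ll = ll
        if use_fast:
            theta_new = _m_step_from_moments(
                mom, sum_gamma, z.shape[0], design, theta, controls
            )
        else:
            theta_new = m_step(z, (gamma, tau1), design, theta, controls)
        par_change = float(np.max(np.abs(theta_new.as_vector() - theta.as_vector())))
        theta = theta_new
    return best_theta, np.asarray(trace), best_ll, len(trace), converged


def _copula_loglik_at(
    transformer: PseudoDataTransformer, theta: ModelParams, design: StudyDesign
) -> float:
    """Copula log-likelihood of the ranks at ``theta`` (pseudo-data refreshed)."""
    z = transformer.transform(theta)
    if _fast.HAVE_NUMBA:
        lab_start = np.array([sl.start for sl in design.lab_slices], dtype=np.int64)
        lab_m = np.array(design.M, dtype=np.int64)
        *_, ll_joint, _, _ = _fast.nested_em_pass(
            z, lab_start, lab_m, theta.pi1, theta.pi11,
            theta.mu01, theta.mu11, theta.sigma11, theta.rho11,
        )
    else:
        *_, ll_joint = e_step(z, theta, design)
    return float(ll_joint) - transformer.log_jacobian(theta)


def _pack_params(theta: ModelParams) -> np.ndarray:
    """Unconstrained reparameterisation: logits for probabilities and
    correlations, logs for the ordered means and the scale."""
    return np.concatenate(
        [
            [special.logit(theta.pi1)],
            special.logit(theta.pi11),
            np.log(theta.mu01),
            np.log(theta.mu11 - theta.mu01),
            np.log(theta.sigma11),
            special.logit(theta.rho11),
        ]
    )


def _unpack_params(v: np.ndarray, L: int) -> ModelParams:
    mu01 = np.exp(v[1 + L : 1 + 2 * L])
    return ModelParams(
        pi1=float(special.expit(v[0])),
        pi11=special.expit(v[1 : 1 + L]),
        mu01=mu01,
        mu11=mu01 + np.exp(v[1 + 2 * L : 1 + 3 * L]),
        sigma11=np.exp(v[1 + 3 * L : 1 + 4 * L]),
        rho11=special.expit(v[1 + 4 * L : 1 + 5 * L]),
    )


def _polish(
    transformer: PseudoDataTransformer,
    theta: ModelParams,
    design: StudyDesign,
    controls: FitControls,
    start_ll: float,
) -> tuple[ModelParams, float]:
    """Nelder-Mead maximisation of the copula log-likelihood from the EM
    solution.  The refresh fixed point is systematically displaced from the
    criterion's maximiser (the marginal re-mapping is not accounted for by
    the EM pass), so a direct search removes that finite-sample bias.
    Frozen ``pi11`` coordinates are kept fixed."""
    from scipy import optimize

    L = design.L
    v0 = _pack_params(theta)
    free = np.ones(v0.size, dtype=bool)
    if controls.freeze_pi11 is not None:
        free[1 : 1 + L] = False

    def neg(vf: np.ndarray) -> float:
        v = v0.copy()
        v[free] = vf
        try:
            return -_copula_loglik_at(transformer, _unpack_params(v, L), design)
        except (ValueError, FloatingPointError):
            return np.inf

    res = optimize.minimize(
        neg,
        v0[free],
        method="Nelder-Mead",
        options=dict(maxfev=controls.polish_maxfev, xatol=1e-5, fatol=1e-6),
    )
    if -res.fun <= start_ll:
        return theta, start_ll
    v = v0.copy()
    v[free] = res.x
    return _unpack_params(v, L), float(-res.fun)


def fit(
    x: ScoreMatrix,
    init: ModelParams | list[tuple[str, ModelParams]] | None = None,
    controls: FitControls | None = None,
) -> FitResult:
    """Fit the nested mixture by multi-start pseudo-EM.

    Parameters
    ----------
    x : ScoreMatrix
        Observed scores (only ranks are used).
    init : ModelParams or list of (label, ModelParams), optional
        A single start, an explicit list of starts, or None for the default
        multi-start schedule (one moment-based + three presets).
    controls : FitControls, optional

    Returns
    -------
    FitResult
        The iterate with the highest observed likelihood across all outer
        iterations of all starts.
    """
    controls = controls or FitControls()
    if init is None:
        starts = default_initializations(x)
    elif isinstance(init, ModelParams):
        starts = [("user", init)]
    else:
        starts = list(init)
    transformer = PseudoDataTransformer(x)
    results = []
    errors = []
    for label, theta0 in starts:
        try:
            theta, trace, best_ll, iters, conv = _fit_single(
                transformer, theta0, x.design, controls
            )
            results.append(FitResult(theta, trace, best_ll, iters, conv, label))
        except Exception as exc:  # pragma: no cover - defensive
            errors.append((label, exc))
    if not results:
        raise RuntimeError(f"all initializations failed: {errors}")
    best = max(results, key=lambda r: r.best_loglik)
    if controls.polish:
        best.params, best.best_loglik = _polish(
            transformer, best.params, x.design, controls, best.best_loglik
        )
    best.all_starts = [
        {"init": r.init_label, "best_loglik": r.best_loglik, "converged": r.converged}
        for r in results
    ]
    return best


def pseudo_data_at(x: ScoreMatrix, params: ModelParams) -> np.ndarray:
    """Pseudo-data evaluated at fitted parameters (for scoring)."""
    return make_pseudo_data(x, params)
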