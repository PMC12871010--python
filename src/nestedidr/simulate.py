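"""Synthetic-data engine for nested multi-lab replicate scores.

Generates candidate scores by the model's two-level process — draw the
replicability label ``G``, then per-lab reproducibility labels ``K``, then
latent equicorrelated normal replicate vectors — plus three controlled
assumption violations used in robustness studies: residual cross-lab
correlation among signal components, correlation among irreproducible-signal
replicates, and a Gumbel (upper-tail dependent) copula for the reproducible
component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .estimation import ScoreMatrix
from .model import ModelParams, StudyDesign

__all__ = [
    "ScenarioConfig",
    "SimTruth",
    "scenario_preset",
    "SCENARIO_TABLE",
    "simulate_dataset",
    "simulate_gumbel_block",
]

#: True parameters of the four standard simulation settings (two labs, two
#: replicates each, n = 5000).  Columns: pi0, per-lab pi01, mu01, mu11,
#: sigma11, rho11.  S1/S2 have a high signal proportion, S3/S4 a low one;
#: S2/S4 degrade lab 2's quality relative to S1/S3.
SCENARIO_TABLE = {
    "S1": dict(pi0=0.3, pi01=(0.2, 0.2), mu01=(1.0, 1.0), mu11=(3.0, 3.0),
               sigma11=(1.0, 1.0), rho11=(0.9, 0.9)),
    "S2": dict(pi0=0.3, pi01=(0.2, 0.5), mu01=(1.0, 1.0), mu11=(3.0, 3.0),
               sigma11=(1.0, 1.4), rho11=(0.9, 0.7)),
    "S3": dict(pi0=0.5, pi01=(0.2, 0.2), mu01=(1.0, 1.0), mu11=(2.0, 2.0),
               sigma11=(1.0, 1.0), rho11=(0.9, 0.9)),
    "S4": dict(pi0=0.5, pi01=(0.2, 0.5), mu01=(1.0, 1.0), mu11=(2.0, 2.0),
               sigma11=(1.0, 1.4), rho11=(0.9, 0.7)),
}

_DISTORTIONS = ("identity", "exp", "logistic", "rank_uniform")


@dataclass
class Violations:
    """Optional deviations from the model's assumptions.

    cross_lab_rho : residual correlation between different labs' signal
        components, induced by a shared latent factor with loading
        ``sqrt(cross_lab_rho)``.
    irrep_within_rho : equicorrelation among the replicates of
        irreproducible genuine signals (the model assumes 0).
    signal_copula : 'gaussian' (model-consistent) or 'gumbel' for the
        reproducible component, with upper-tail dependence ``gumbel_theta``.
    """

    cross_lab_rho: float = 0.0
    irrep_within_rho: float = 0.0
    signal_copula: str = "gaussian"
    gumbel_theta: float = 2.0

    def validate(self, design: StudyDesign) -> None:
        if not (0.0 <= self.cross_lab_rho < 1.0):
            raise ValueError("cross_lab_rho must lie in [0, 1)")
        for m in design.M:
            lo = -1.0 / max(m - 1, 1)
            if not (lo < self.irrep_within_rho < 1.0):
                raise ValueError(
                    f"irrep_within_rho must lie in ({lo:.3f}, 1) for M_l={m}"
                )
        if self.signal_copula not in ("gaussian", "gumbel"):
            raise ValueError("signal_copula must be 'gaussian' or 'gumbel'")
        if self.signal_copula == "gumbel" and self.gumbel_theta < 1.0:
            raise ValueError("gumbel_theta must be >= 1")


@dataclass
class ScenarioConfig:
    """Full specification of one synthetic dataset."""

    design: StudyDesign
    params: ModelParams
    n: int = 5000
    seed: int = 0
    violations: Violations = field(default_factory=Violations)
    #: per-replicate monotone output transform, or a single name for all
    output_transform: str | tuple[str, ...] = "identity"

    def __post_init__(self):
        self.params.validate()
        self.violations.validate(self.design)
        if isinstance(self.output_transform, str):
            self.output_transform = (self.output_transform,) * self.design.P
        if len(self.output_transform) != self.design.P:
            raise ValueError("need one output transform per replicate column")
        for t in self.output_transform:
            if t not in _DISTORTIONS:
                raise ValueError(f"unknown transform {t!r}; choose from {_DISTORTIONS}")


@dataclass
class SimTruth:
    """Ground-truth latent labels of a simulated dataset."""

    G: np.ndarray  # (n,) 1 = genuine signal
    K: np.ndarray  # (n, L) 1 = reproducible in lab l; 0 wherever G = 0

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=int)
        self.K = np.atleast_2d(np.asarray(self.K, dtype=int))
        if np.any(self.K[self.G == 0] != 0):
            raise ValueError("noise candidates cannot be reproducible")


def scenario_preset(name: str, n: int = 5000, seed: int = 0) -> ScenarioConfig:
    """Standard two-lab, two-replicate simulation setting S1-S4."""
    if name not in SCENARIO_TABLE:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIO_TABLE)}")
    row = SCENARIO_TABLE[name]
    params = ModelParams(
        pi1=1.0 - row["pi0"],
        pi11=1.0 - np.asarray(row["pi01"]),
        mu01=np.asarray(row["mu01"]),
        mu11=np.asarray(row["mu11"]),
        sigma11=np.asarray(row["sigma11"]),
        rho11=np.asarray(row["rho11"]),
    )
    return ScenarioConfig(design=StudyDesign(M=(2, 2)), params=params, n=n, seed=seed)


def simulate_gumbel_block(
    n_rows: int, dim: int, theta: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Sample from a ``dim``-variate Gumbel copula (uniform margins).

    Uses the Marshall-Olkin construction: with ``S`` positive stable of
    index ``1/theta`` and i.i.d. exponentials ``E_j``,
    ``U_j = exp(-(E_j/S)^{1/theta})``.  ``theta = 1`` is independence;
    Kendall's tau equals ``1 - 1/theta``.
    """
    if theta < 1.0:
        raise ValueError("Gumbel dependence parameter theta must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e = rng.standard_exponential((n_rows, dim))
    if theta == 1.0:
        return np.exp(-e)
    alpha = 1.0 / theta
    # Chambers-Mallows-Stuck sampler for positive stable(alpha)
    v = rng.uniform(0.0, np.pi, n_rows)
    w = rng.standard_exponential(n_rows)
    s = (
        np.sin(alpha * v) / np.power(np.sin(v), 1.0 / alpha)
        * np.power(np.sin((1.0 - alpha) * v) / w, (1.0 - alpha) / alpha)
    )
    return np.exp(-np.power(e / s[:, None], alpha))


def _equicorr_normal(rng, n, m, rho) -> np.ndarray:
    """Standardised equicorrelated normals, exact for -1/(m-1) < rho < 1.

    Splits i.i.d. draws into the row-mean direction (eigenvalue
    ``1+(m-1)rho``) and its orthogonal complement (eigenvalue ``1-rho``) and
    rescales each part.
    """
    eps = rng.standard_normal((n, m))
    if rho == 0.0 or m == 1:
        return eps
    ebar = eps.mean(axis=1, keepdims=True)
    a = np.sqrt(1.0 - rho)
    b = np.sqrt(1.0 + (m - 1) * rho)
    return a * (eps - ebar) + b * ebar


def simulate_dataset(config: ScenarioConfig) -> tuple[ScoreMatrix, SimTruth]:
    """Draw one synthetic dataset with ground-truth labels.

    Bit-reproducible for a fixed config (all randomness flows from
    ``config.seed``).
    """
    rng = np.random.default_rng(config.seed)
    p, d, v = config.params, config.design, config.violations
    n, L = config.n, d.L

    G = (rng.uniform(size=n) < p.pi1).astype(int)
    K = np.zeros((n, L), dtype=int)
    for l in range(L):
        K[:, l] = (rng.uniform(size=n) < p.pi11[l]) & (G == 1)

    z = np.empty((n, d.P))
    shared = rng.standard_normal(n) if v.cross_lab_rho > 0 else None
    for l, sl in enumerate(d.lab_slices):
        m = d.M[l]
        block = np.empty((n, m))
        noise = G == 0
        irrep = (G == 1) & (K[:, l] == 0)
        rep = (G == 1) & (K[:, l] == 1)
        # noise: independent standard normal
        block[noise] = rng.standard_normal((int(noise.sum()), m))
        # irreproducible genuine: mean mu01, unit SD, optional equicorrelation
        block[irrep] = p.mu01[l] + _equicorr_normal(
            rng, int(irrep.sum()), m, v.irrep_within_rho
        )
        # reproducible genuine: equicorrelated or Gumbel-coupled
        n_rep = int(rep.sum())
        if v.signal_copula == "gumbel":
            u = simulate_gumbel_block(n_rep, m, v.gumbel_theta, rng)
            std_block = special.ndtri(u)
        else:
            std_block = _equicorr_normal(rng, n_rep, m, p.rho11[l])
        if v.cross_lab_rho > 0:
            # shared factor across labs; rescale to keep unit marginal SD
            lam = v.cross_lab_rho
            std_block = np.sqrt(lam) * shared[rep][:, None] + np.sqrt(1 - lam) * std_block
            block[irrep] = p.mu01[l] + (
                np.sqrt(lam) * shared[irrep][:, None]
                + np.sqrt(1 - lam) * (block[irrep] - p.mu01[l])
            )
        block[rep] = p.mu11[l] + p.sigma11[l] * std_block
        z[:, sl] = block

    x = np.empty_like(z)
    for j, t in enumerate(config.output_transform):
        x[:, j] = _apply_transform(z[:, j], t)

    ids = np.array([f"cand_{i}" for i in range(n)])
    return ScoreMatrix(x, d, ids), SimTruth(G, K)


def _apply_transform(col: np.ndarray, name: str) -> np.ndarray:
    """Strictly increasing per-column output distortions (rank-preserving)."""
    if name == "identity":
        return col
    if name == "exp":
        return np.exp(col / 2.0)
    if name == "logistic":
        return 1.0 / (1.0 + np.exp(-col))
    if name == "rank_uniform":
        return stats.rankdata(col, method="average") / (col.size + 1.0)
    raise ValueError(name)
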