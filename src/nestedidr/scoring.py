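"""Posterior reproducibility/replicability scores and controlled selection.

``idr_between`` is the posterior probability that a candidate is noise (not
replicable across labs) given all labs' data; ``idr_within(l)`` is the
posterior probability that a genuine candidate is irreproducible in lab
``l``, given only that lab's data.  Selection at level ``alpha`` keeps the
largest ascending-sorted prefix whose mean posterior stays below ``alpha``,
which controls the expected rate of irreplicable (or irreproducible)
discoveries in the selected set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ModelParams,
    StudyDesign,
    candidate_log_mixture,
    component_log_density,
)

__all__ = [
    "PosteriorScores",
    "idr_between",
    "idr_within",
    "compute_scores",
    "select_at_level",
    "prefix_mean_alpha",
]


@dataclass
class PosteriorScores:
    """Per-candidate posterior scores, aligned with the input rows."""

    idr_between: np.ndarray  # (n,) posterior P(noise | all data)
    idr_within: np.ndarray  # (n, L) posterior P(irreproducible in lab l | genuine)
    candidate_ids: np.ndarray = None

    def __post_init__(self):
        self.idr_between = np.asarray(self.idr_between, dtype=float)
        self.idr_within = np.atleast_2d(np.asarray(self.idr_within, dtype=float))
        if self.candidate_ids is None:
            self.candidate_ids = np.array(
                [f"cand_{i}" for i in range(self.idr_between.shape[0])]
            )


def idr_between(z: np.ndarray, params: ModelParams, design: StudyDesign) -> np.ndarray:
    """Posterior probability of the noise state given all labs' pseudo-data.

    Equals ``pi0 prod_l h00 / (full mixture density)``, i.e. ``1 - gamma``
    from the E-step.
    """
    log_noise, _, log_mix = candidate_log_mixture(z, params, design)
    return np.exp(log_noise - log_mix)


def idr_within(z_lab: np.ndarray, params: ModelParams, lab: int) -> np.ndarray:
    """Posterior probability of irreproducibility in one lab, given G=1.

    Uses only lab ``lab``'s replicate block; other labs' data are irrelevant
    by conditional independence.
    """
    z_lab = np.atleast_2d(np.asarray(z_lab, dtype=float))
    pi11 = params.pi11[lab]
    a = np.log1p(-pi11) + component_log_density(z_lab, 1, 0, params, lab)
    b = np.log(pi11) + component_log_density(z_lab, 1, 1, params, lab)
    return np.exp(a - np.logaddexp(a, b))


def compute_scores(
    z: np.ndarray,
    params: ModelParams,
    design: StudyDesign,
    candidate_ids=None,
) -> PosteriorScores:
    """Both posterior score families for every candidate."""
    between = idr_between(z, params, design)
    within = np.column_stack(
        [idr_within(z[:, sl], params, l) for l, sl in enumerate(design.lab_slices)]
    )
    return PosteriorScores(between, within, candidate_ids)


def select_at_level(idr_values: np.ndarray, alpha: float) -> np.ndarray:
    """Indices selected at expected-irreproducibility level ``alpha``.

    Sorts the posteriors ascending (stable, so ties keep input order) and
    keeps the largest prefix whose running mean does not exceed ``alpha``;
    the mean posterior of the returned set is therefore at most ``alpha``.
    """
    idr_values = np.asarray(idr_values, dtype=float)
    if idr_values.size == 0:
        raise ValueError("empty score vector")
    if not np.all(np.isfinite(idr_values)):
        raise ValueError("scores must be finite")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    order = np.argsort(idr_values, kind="stable")
    prefix_means = np.cumsum(idr_values[order]) / np.arange(1, idr_values.size + 1)
    # prefix means over an ascending sequence are non-decreasing
    s = int(np.searchsorted(prefix_means, alpha, side="right"))
    return order[:s]


def prefix_mean_alpha(idr_values: np.ndarray) -> np.ndarray:
    """Smallest level at which each candidate would be selected.

    The running prefix mean of the ascending-sorted posteriors, mapped back
    to input order — a q-value-like quantity for the selection rule.
    """
    idr_values = np.asarray(idr_values, dtype=float)
    order = np.argsort(idr_values, kind="stable")
    prefix_means = np.cumsum(idr_values[order]) / np.arange(1, idr_values.size + 1)
    out = np.empty_like(prefix_means)
    out[order] = prefix_means
    return out
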