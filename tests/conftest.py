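"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from nestedidr import ModelParams, ScoreMatrix, StudyDesign


@pytest.fixture
def design22() -> StudyDesign:
    return StudyDesign(M=(2, 2))


@pytest.fixture
def params22() -> ModelParams:
    """Valid two-lab parameter set used across tests."""
    return ModelParams(
        pi1=0.7,
        pi11=np.array([0.8, 0.5]),
        mu01=np.array([1.0, 1.0]),
        mu11=np.array([3.0, 3.0]),
        sigma11=np.array([1.0, 1.4]),
        rho11=np.array([0.9, 0.7]),
    )


def random_params(rng: np.random.Generator, L: int) -> ModelParams:
    """Random valid parameter set for property tests."""
    mu01 = rng.uniform(0.3, 1.5, L)
    return ModelParams(
        pi1=rng.uniform(0.2, 0.8),
        pi11=rng.uniform(0.3, 0.9, L),
        mu01=mu01,
        mu11=mu01 + rng.uniform(0.5, 3.0, L),
        sigma11=rng.uniform(0.6, 1.6, L),
        rho11=rng.uniform(0.1, 0.9, L),
    )


def small_matrix(rng: np.random.Generator, n: int, design: StudyDesign) -> ScoreMatrix:
    return ScoreMatrix(rng.standard_normal((n, design.P)), design)
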