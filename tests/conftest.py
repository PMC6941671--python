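"""Shared fixtures: random material states and finite-difference oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ventriq.constitutive import (
    ActiveParams,
    DeformationState,
    PassiveParams,
    passive_strain_energy,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def random_incompressible_state(rng: np.random.Generator, scale: float = 0.15) -> DeformationState:
    """Random isochoric deformation with orthonormal fiber/sheet directions."""
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    F = F / np.linalg.det(F) ** (1.0 / 3.0)
    f0 = rng.standard_normal(3)
    f0 /= np.linalg.norm(f0)
    v = rng.standard_normal(3)
    s0 = v - (v @ f0) * f0
    s0 /= np.linalg.norm(s0)
    return DeformationState(F=F, f0=f0, s0=s0)


def random_passive_params(rng: np.random.Generator) -> PassiveParams:
    return PassiveParams(
        a=rng.uniform(0.2, 5.0), b=rng.uniform(4.0, 12.0),
        a_f=rng.uniform(0.2, 20.0), b_f=rng.uniform(8.0, 20.0),
        a_s=rng.uniform(0.1, 7.0), b_s=rng.uniform(6.0, 14.0),
        a_fs=rng.uniform(0.05, 4.0), b_fs=rng.uniform(6.0, 14.0),
        D=2.0e-4,
    )


def fd_cauchy_stress(state: DeformationState, p: PassiveParams, h: float = 1e-6) -> np.ndarray:
    """Independent stress oracle: numerically differentiate the strain energy.

    First Piola stress P_ij = dW/dF_ij by central differences, then
    sigma = P F^T / J.
    """
    F0 = state.F
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            for sgn in (1.0, -1.0):
                F = F0.copy()
                F[i, j] += sgn * h
                st = DeformationState(F=F, f0=state.f0, s0=state.s0)
                P[i, j] += sgn * sum(passive_strain_energy(st, p)) / (2.0 * h)
    J = float(np.linalg.det(F0))
    return P @ F0.T / J


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture
def passive() -> PassiveParams:
    return PassiveParams()


@pytest.fixture
def active() -> ActiveParams:
    return ActiveParams()
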