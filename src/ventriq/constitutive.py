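"""Material-point mechanics of passive and active myocardium.

Passive myocardium is modelled as an orthotropic hyperelastic solid of the
Holzapfel–Ogden family: an exponential isotropic matrix term in the first
invariant ``I1``, exponential fiber and sheet reinforcement terms in the
squared stretches ``I4f``, ``I4s``, and an exponential fiber–sheet coupling
term in ``I8fs``, plus a volumetric penalty::

    psi_dev = a/(2b) exp[b (I1 - 3)]
            + sum_{i=f,s} a_i/(2 b_i) { exp[b_i (I4i - 1)^2] - 1 }
            + a_fs/(2 b_fs) { exp[b_fs I8fs^2] - 1 }
    psi_vol = (1/D) [ (J^2 - 1)/2 - ln J ]

The deviatoric part is evaluated on isochoric invariants (``C_bar =
J^{-2/3} C``) with a deviatoric stress projection, so the undeformed state
is exactly stress free.  Fiber and sheet terms engage only in tension
(``I4i > 1``): myocytes and collagen sheets do not stiffen in compression.

Active contraction follows a Hill-type length- and calcium-dependent
tension model.  The actively generated fiber tension is

    T0 = Tmax * Ca0^2 / (Ca0^2 + ECa50^2) * Ct

where ``Ct`` is a raised-cosine twitch in time (peak at ``t0``, linear
length-dependent relaxation duration ``tr = m_relax*l + b_relax``) and
``ECa50`` is the length-dependent calcium sensitivity

    ECa50 = Ca0max / sqrt(exp[B (l - l0)] - 1)

with sarcomere length ``l = lR * sqrt(2 Eff + 1)`` computed from the
Lagrangian fiber strain.  Below the zero-tension length ``l0`` the tension
is identically zero.  Total Cauchy stress is the passive stress plus a
rank-1 active stress ``T0 * f_hat (x) f_hat`` along the deformed fiber
direction.

Units: stresses in kPa, sarcomere lengths in um, times in s, calcium
concentrations in uM.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Tuple

import numpy as np

__all__ = [
    "ConstitutiveError",
    "InvalidDeformationError",
    "InvalidStrainError",
    "InvalidParameterError",
    "SaturationError",
    "PassiveParams",
    "ActiveParams",
    "DeformationState",
    "InvariantSet",
    "ActivationState",
    "invariants",
    "passive_strain_energy",
    "passive_cauchy_stress",
    "sarcomere_length",
    "relaxation_duration",
    "ct_waveform",
    "eca50",
    "active_tension",
    "activation_state",
    "fiber_strain",
    "total_cauchy_stress",
    "KPA_PER_MMHG",
    "MMHG_PER_KPA",
]

KPA_PER_MMHG = 0.1333223684
MMHG_PER_KPA = 1.0 / KPA_PER_MMHG

#: largest admissible argument to exp() in the energy/stress terms
_EXP_MAX = 350.0


class ConstitutiveError(ValueError):
    """Base class for constitutive-model errors."""


class InvalidDeformationError(ConstitutiveError):
    """Deformation gradient is non-finite or has non-positive determinant."""


class InvalidStrainError(ConstitutiveError):
    """Fiber strain outside the kinematically admissible range."""


class InvalidParameterError(ConstitutiveError):
    """A material parameter violates its admissibility constraint."""


class SaturationError(ConstitutiveError):
    """An exponential energy term overflowed; names the offending term."""


@dataclass(frozen=True)
class PassiveParams:
    """Constants of the passive orthotropic law.

    ``a``-type constants are stress-like (kPa), ``b``-type exponents are
    dimensionless, and ``D`` (kPa^-1) is the volumetric penalty constant
    multiplying ``psi_vol`` as ``1/D``.
    """

    a: float = 1.0
    b: float = 8.023
    a_f: float = 5.0
    b_f: float = 16.026
    a_s: float = 1.0
    b_s: float = 11.120
    a_fs: float = 0.5
    b_fs: float = 11.436
    D: float = 2.0e-4  # kPa^-1  (== 0.2 MPa^-1)

    def __post_init__(self) -> None:
        for name in ("a", "a_f", "a_s", "a_fs"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        for name in ("b", "b_f", "b_s", "b_fs"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.D <= 0:
            raise InvalidParameterError("D must be > 0")

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "PassiveParams":
        return cls(**{f.name: d[f.name] for f in fields(cls) if f.name in d})


@dataclass(frozen=True)
class ActiveParams:
    """Constants of the active tension model.

    Tmax (kPa) is the isometric tension at the longest sarcomere length
    and peak calcium.  Ca0 and Ca0max (uM) are the peak and maximum-peak
    intracellular calcium concentrations; only the ratio of Ca0 to the
    length-dependent sensitivity ECa50 enters the tension.  B (um^-1)
    shapes the tension-length relation, l0 (um) is the zero-active-tension
    sarcomere length and lR (um) the stress-free reference length.  t0 (s)
    is the time to peak twitch tension; m_relax (s/um) and b_relax (s) set
    the linear length dependence of the relaxation duration.
    """

    Tmax: float = 135.0
    Ca0: float = 4.35
    Ca0max: float = 4.35
    B: float = 4.75
    l0: float = 1.58
    lR: float = 1.85
    t0: float = 0.15
    m_relax: float = 0.05
    b_relax: float = 0.0

    def __post_init__(self) -> None:
        if self.Tmax < 0:
            raise InvalidParameterError("Tmax must be >= 0")
        if self.Ca0 <= 0 or self.Ca0max <= 0:
            raise InvalidParameterError("Ca0, Ca0max must be > 0")
        if self.B <= 0:
            raise InvalidParameterError("B must be > 0")
        if self.l0 <= 0 or self.lR <= 0:
            raise InvalidParameterError("l0 and lR must be > 0")
        if self.t0 <= 0:
            raise InvalidParameterError("t0 must be > 0")
        # tr must be positive over admissible lengths; negative slopes are
        # re-checked per call in relaxation_duration.
        if self.m_relax <= 0 and self.b_relax <= 0:
            raise InvalidParameterError("tr = m_relax*l + b_relax must be > 0")

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ActiveParams":
        return cls(**{f.name: d[f.name] for f in fields(cls) if f.name in d})


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = float(np.linalg.norm(v))
    if not np.isfinite(n) or n == 0.0:
        raise InvalidDeformationError("direction vector must be nonzero and finite")
    return v / n


@dataclass(frozen=True)
class DeformationState:
    """Local deformation: gradient F plus fiber/sheet material directions.

    ``f0`` and ``s0`` are normalized at construction and must be mutually
    orthogonal.  Derived quantities ``C = F^T F`` and ``J = det F`` are
    exposed as properties; ``J <= 0`` or a non-finite F is rejected.
    """

    F: np.ndarray
    f0: np.ndarray
    s0: np.ndarray

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if F.shape != (3, 3):
            raise InvalidDeformationError("F must be 3x3")
        if not np.all(np.isfinite(F)):
            raise InvalidDeformationError("F must be finite")
        if np.linalg.det(F) <= 0:
            raise InvalidDeformationError("det F must be > 0")
        f0 = _unit(self.f0)
        s0 = _unit(self.s0)
        if abs(float(f0 @ s0)) > 1e-8:
            raise InvalidDeformationError("f0 and s0 must be orthogonal")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "f0", f0)
        object.__setattr__(self, "s0", s0)

    @property
    def C(self) -> np.ndarray:
        return self.F.T @ self.F

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))


@dataclass(frozen=True)
class InvariantSet:
    """Isochoric strain invariants entering the deviatoric energy."""

    I1: float
    I4f: float
    I4s: float
    I8fs: float


@dataclass(frozen=True)
class ActivationState:
    """Snapshot of the active-tension pipeline at one material point."""

    t: float
    Eff: float
    l: float
    Ct: float
    tr: float
    ECa50: float
    T0: float


def invariants(state: DeformationState) -> InvariantSet:
    """Isochoric invariants of the right Cauchy–Green tensor.

    Computed on ``C_bar = J^{-2/3} C`` so that pure volume change leaves
    the deviatoric energy untouched.
    """
    J = state.J
    Cb = state.C * J ** (-2.0 / 3.0)
    f0, s0 = state.f0, state.s0
    return InvariantSet(
        I1=float(np.trace(Cb)),
        I4f=float(f0 @ Cb @ f0),
        I4s=float(s0 @ Cb @ s0),
        I8fs=float(f0 @ Cb @ s0),
    )


def _checked_exp(x: float, term: str) -> float:
    if x > _EXP_MAX:
        raise SaturationError(
            f"exponential overflow in the {term} term (argument {x:.3g})"
        )
    return float(np.exp(x))


def passive_strain_energy(
    state: DeformationState, p: PassiveParams
) -> Tuple[float, float]:
    """Deviatoric and volumetric strain-energy densities (kPa).

    The fiber and sheet exponentials contribute only when the respective
    isochoric squared stretch exceeds 1 (tension-only reinforcement).
    """
    inv = invariants(state)
    psi = p.a / (2.0 * p.b) * _checked_exp(p.b * (inv.I1 - 3.0), "isotropic")
    if inv.I4f > 1.0:
        e4f = inv.I4f - 1.0
        psi += p.a_f / (2.0 * p.b_f) * (
            _checked_exp(p.b_f * e4f * e4f, "fiber") - 1.0
        )
    if inv.I4s > 1.0:
        e4s = inv.I4s - 1.0
        psi += p.a_s / (2.0 * p.b_s) * (
            _checked_exp(p.b_s * e4s * e4s, "sheet") - 1.0
        )
    psi += p.a_fs / (2.0 * p.b_fs) * (
        _checked_exp(p.b_fs * inv.I8fs**2, "fiber-sheet") - 1.0
    )
    J = state.J
    psi_vol = (1.0 / p.D) * ((J * J - 1.0) / 2.0 - np.log(J))
    return float(psi), float(psi_vol)


def _dpsi_dinvariants(inv: InvariantSet, p: PassiveParams):
    """Partials of psi_dev w.r.t. the isochoric invariants."""
    psi1 = 0.5 * p.a * _checked_exp(p.b * (inv.I1 - 3.0), "isotropic")
    if inv.I4f > 1.0:
        e = inv.I4f - 1.0
        psi4f = p.a_f * e * _checked_exp(p.b_f * e * e, "fiber")
    else:
        psi4f = 0.0
    if inv.I4s > 1.0:
        e = inv.I4s - 1.0
        psi4s = p.a_s * e * _checked_exp(p.b_s * e * e, "sheet")
    else:
        psi4s = 0.0
    psi8 = p.a_fs * inv.I8fs * _checked_exp(p.b_fs * inv.I8fs**2, "fiber-sheet")
    return psi1, psi4f, psi4s, psi8


def passive_cauchy_stress(state: DeformationState, p: PassiveParams) -> np.ndarray:
    """Closed-form passive Cauchy stress (kPa), symmetric 3x3.

    sigma = (2/J) dev[ F_bar (d psi_dev / d C_bar) F_bar^T ]
          + (d psi_vol / d J) I
    """
    J = state.J
    Fb = state.F * J ** (-1.0 / 3.0)
    Cb = Fb.T @ Fb
    f0, s0 = state.f0, state.s0
    inv = InvariantSet(
        I1=float(np.trace(Cb)),
        I4f=float(f0 @ Cb @ f0),
        I4s=float(s0 @ Cb @ s0),
        I8fs=float(f0 @ Cb @ s0),
    )
    psi1, psi4f, psi4s, psi8 = _dpsi_dinvariants(inv, p)
    dpsi_dCb = (
        psi1 * np.eye(3)
        + psi4f * np.outer(f0, f0)
        + psi4s * np.outer(s0, s0)
        + psi8 * 0.5 * (np.outer(f0, s0) + np.outer(s0, f0))
    )
    tau_bar = 2.0 * Fb @ dpsi_dCb @ Fb.T
    dev = tau_bar - (np.trace(tau_bar) / 3.0) * np.eye(3)
    sigma = dev / J + (1.0 / p.D) * (J - 1.0 / J) * np.eye(3)
    return 0.5 * (sigma + sigma.T)


def sarcomere_length(Eff, lR):
    """Sarcomere length l = lR * sqrt(2*Eff + 1) from Lagrangian fiber strain."""
    Eff = np.asarray(Eff, dtype=float)
    arg = 2.0 * Eff + 1.0
    if np.any(arg <= 0.0):
        raise InvalidStrainError("2*Eff + 1 must be > 0")
    out = lR * np.sqrt(arg)
    return float(out) if out.ndim == 0 else out


def relaxation_duration(l, p: ActiveParams):
    """Relaxation duration tr = m_relax * l + b_relax (s); must be positive."""
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0.0):
        raise InvalidStrainError("sarcomere length must be > 0")
    tr = p.m_relax * l + p.b_relax
    if np.any(tr <= 0.0):
        raise InvalidParameterError("tr = m_relax*l + b_relax must be > 0")
    return float(tr) if tr.ndim == 0 else tr


def ct_waveform(t, t0: float, tr):
    """Raised-cosine twitch Ct(t) in [0, 1].

    Ct = (1 - cos w)/2 with w = pi*t/t0 during the upstroke (0 <= t <= t0),
    w = pi*(t - t0 + tr)/tr during relaxation (t0 <= t <= t0 + tr), and
    Ct = 0 once t >= t0 + tr.  Continuous, peaking at exactly 1 at t = t0.
    """
    t = np.asarray(t, dtype=float)
    tr = np.asarray(tr, dtype=float)
    if np.any(t < 0.0):
        raise ConstitutiveError("t must be >= 0")
    if t0 <= 0 or np.any(tr <= 0.0):
        raise InvalidParameterError("t0 and tr must be > 0")
    w_up = np.pi * t / t0
    with np.errstate(invalid="ignore", divide="ignore"):
        w_down = np.pi * (t - t0 + tr) / tr
    w = np.where(t <= t0, w_up, w_down)
    ct = 0.5 * (1.0 - np.cos(w))
    ct = np.where(t >= t0 + tr, 0.0, ct)
    out = np.clip(ct, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def eca50(l, p: ActiveParams):
    """Length-dependent calcium sensitivity ECa50 (uM).

    ECa50 = Ca0max / sqrt(exp[B (l - l0)] - 1).  For l <= l0 the formula is
    singular; returns +inf there, signalling the zero-tension regime to the
    caller rather than raising.
    """
    l = np.asarray(l, dtype=float)
    out = np.full(l.shape, np.inf)
    mask = l > p.l0
    if np.any(mask):
        denom = np.expm1(p.B * (l[mask] - p.l0))
        out[mask] = p.Ca0max / np.sqrt(denom)
    return float(out) if out.ndim == 0 else out


def fiber_strain(state: DeformationState) -> float:
    """Lagrangian strain along the fiber direction, Eff = (f0.C f0 - 1)/2.

    Uses the full (not isochoric) C: sarcomere length is a physical length.
    """
    return float((state.f0 @ state.C @ state.f0 - 1.0) / 2.0)


def active_tension(t, Eff, p: ActiveParams):
    """Active fiber tension T0 (kPa) at time t and fiber strain Eff.

    Composes the sarcomere length, relaxation duration, twitch waveform and
    calcium sensitivity; T0 = 0 for l <= l0 and for t >= t0 + tr, and never
    exceeds Tmax.
    """
    t_arr = np.asarray(t, dtype=float)
    Eff_arr = np.asarray(Eff, dtype=float)
    t_b, Eff_b = np.broadcast_arrays(t_arr, Eff_arr)
    l = sarcomere_length(Eff_b, p.lR)
    l = np.asarray(l, dtype=float)
    tr = relaxation_duration(l, p)
    ct = ct_waveform(t_b, p.t0, tr)
    e50 = np.asarray(eca50(l, p), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        hill = p.Ca0**2 / (p.Ca0**2 + e50**2)
    hill = np.where(np.isinf(e50), 0.0, hill)
    T0 = p.Tmax * hill * np.asarray(ct, dtype=float)
    T0 = np.where(l <= p.l0, 0.0, T0)
    return float(T0) if T0.ndim == 0 else T0


def activation_state(t: float, Eff: float, p: ActiveParams) -> ActivationState:
    """Assemble the full activation snapshot at one material point.

    Exposes the intermediate quantities of the tension pipeline (sarcomere
    length, twitch value, relaxation duration, calcium sensitivity) for
    inspection and reporting; ``active_tension`` computes the same T0.
    """
    l = float(sarcomere_length(Eff, p.lR))
    tr = float(relaxation_duration(l, p))
    return ActivationState(
        t=float(t),
        Eff=float(Eff),
        l=l,
        Ct=float(ct_waveform(t, p.t0, tr)),
        tr=tr,
        ECa50=float(eca50(l, p)),
        T0=float(active_tension(t, Eff, p)),
    )


def total_cauchy_stress(
    state: DeformationState, t: float, pp: PassiveParams, ap: ActiveParams
) -> np.ndarray:
    """Total Cauchy stress: passive plus rank-1 active tension (kPa).

    The active tension acts along the deformed unit fiber direction
    f_hat = F f0 / |F f0|.
    """
    sigma = passive_cauchy_stress(state, pp)
    T0 = active_tension(t, fiber_strain(state), ap)
    if T0 != 0.0:
        fhat = state.F @ state.f0
        fhat = fhat / np.linalg.norm(fhat)
        sigma = sigma + T0 * np.outer(fhat, fhat)
    return sigma
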