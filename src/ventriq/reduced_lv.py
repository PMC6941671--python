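"""Reduced-order ventricular mechanics: the package's truth model.

Two desk-scale stand-ins for a full 3-D finite-element heart replace the
expensive solves while keeping the constitutive equations untouched:

* **Pressure/volume generator** — each ventricle is a thick-walled
  incompressible sphere of the passive/active myocardium of
  :mod:`ventriq.constitutive`.  Cavity pressure follows from radial
  equilibrium integrated across transmural quadrature layers.  The two
  chambers are coupled in a closed loop through diode valves, a
  three-element Windkessel afterload per chamber, and systemic/pulmonary
  venous compartments, so right-ventricular properties genuinely influence
  left-ventricular preload.  One cardiac cycle is reported on a fixed
  401-point time grid after a few settling cycles.

* **End-diastolic stress generator** — the left ventricle is a truncated
  prolate spheroid shell inflated incompressibly by a single scalar
  (equatorial stretch); the scalar is solved from a global energy balance
  ``dW/dkappa = P_ED * dV/dkappa``.  Passive Cauchy stresses are then
  evaluated at 576 endocardial element centroids with a helix-angle
  fiber field, giving fiber (S11), cross-fiber (S22) and shear (S12)
  components.

Units: pressures in mmHg at the circulation interface, stresses in kPa,
lengths in mm, volumes in ml, time in s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constitutive import (
    ActiveParams,
    ConstitutiveError,
    DeformationState,
    KPA_PER_MMHG,
    MMHG_PER_KPA,
    PassiveParams,
    active_tension,
    passive_cauchy_stress,
    passive_strain_energy,
)

__all__ = [
    "SimulationError",
    "IntegrationError",
    "ConfigError",
    "ChamberGeometry",
    "ChamberSpec",
    "CirculationParams",
    "PVTrace",
    "SpheroidGeometry",
    "EDMesh",
    "StressRecord",
    "sphere_layer_deformation",
    "chamber_pressure",
    "wall_strain_energy",
    "simulate_cycle",
    "build_ed_mesh",
    "ed_inflation_solve",
    "ed_stress_field",
    "generate_pv_dataset",
    "generate_stress_dataset",
    "PV_FEATURES",
    "STRESS_FEATURES",
]

PV_FEATURES = ("l0_LV", "l0_RV", "t0_LV", "t0_RV", "Tmax_LV", "Tmax_RV", "t")
STRESS_FEATURES = ("a", "a_s", "a_f", "a_fs", "r", "theta", "z")

ML_PER_MM3 = 1.0e-3


class SimulationError(RuntimeError):
    """A reduced-order simulation failed to produce a valid state."""


class IntegrationError(SimulationError):
    """Time integration of the chamber-circulation system failed."""


class ConfigError(ValueError):
    """Inconsistent geometry or circulation configuration."""


# ---------------------------------------------------------------------------
# spherical chamber
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChamberGeometry:
    """Thick-walled spherical chamber: unloaded inner radius (mm), constant
    wall volume (mm^3) and the number of transmural quadrature layers."""

    Ri: float
    wall_volume: float
    n_layers: int = 5

    def __post_init__(self) -> None:
        if self.Ri <= 0 or self.wall_volume <= 0:
            raise ConfigError("Ri and wall_volume must be > 0")
        if self.n_layers < 3:
            raise ConfigError("n_layers must be >= 3")

    @property
    def Ro(self) -> float:
        """Unloaded outer radius (mm)."""
        return (self.Ri**3 + 3.0 * self.wall_volume / (4.0 * math.pi)) ** (1.0 / 3.0)

    @property
    def cavity_volume0(self) -> float:
        """Unloaded cavity volume (ml)."""
        return 4.0 / 3.0 * math.pi * self.Ri**3 * ML_PER_MM3

    def layer_midpoints(self) -> Tuple[np.ndarray, float]:
        """Midpoint reference radii of the quadrature layers and their width."""
        dR = (self.Ro - self.Ri) / self.n_layers
        R0 = self.Ri + (np.arange(self.n_layers) + 0.5) * dR
        return R0, dR


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry plus material parameters for one ventricle."""

    geometry: ChamberGeometry
    passive: PassiveParams
    active: ActiveParams


def sphere_layer_deformation(
    ri: float, layer_R0: float, geom: ChamberGeometry
) -> DeformationState:
    """Incompressible spherical inflation kinematics at one wall layer.

    The layer at reference radius ``layer_R0`` moves to current radius
    ``r`` with ``r^3 = ri^3 + R0^3 - Ri^3`` (constant enclosed wall
    volume); the deformation gradient in the local (radial, fiber, sheet)
    frame is ``diag(lambda^-2, lambda, lambda)`` with tangential stretch
    ``lambda = r / R0``, hence det F = 1 exactly.
    """
    if ri <= 0:
        raise SimulationError("inner radius must be > 0")
    r3 = ri**3 + layer_R0**3 - geom.Ri**3
    if r3 <= 0:
        raise SimulationError("layer collapsed: non-positive current radius")
    lam = r3 ** (1.0 / 3.0) / layer_R0
    F = np.diag([lam**-2, lam, lam])
    return DeformationState(F=F, f0=np.array([0.0, 1.0, 0.0]), s0=np.array([0.0, 0.0, 1.0]))


def _sphere_lambdas(ri: float, geom: ChamberGeometry) -> Tuple[np.ndarray, np.ndarray, float]:
    """Current radii and tangential stretches at the quadrature layers."""
    R0, dR = geom.layer_midpoints()
    r = np.cbrt(ri**3 + R0**3 - geom.Ri**3)
    return r, r / R0, dR


def chamber_pressure(
    ri: float,
    t: float,
    pp: PassiveParams,
    ap: ActiveParams,
    geom: ChamberGeometry,
) -> float:
    """Cavity pressure (mmHg) of the inflated sphere at time ``t``.

    Thick-wall radial equilibrium gives
    ``P = int_{ri}^{ro} (sigma_ff + sigma_ss - 2 sigma_rr) / r  dr``,
    evaluated by midpoint quadrature over the reference layers.  The
    integrand is invariant to the indeterminate incompressibility pressure,
    so it is assembled directly from the deviatoric stress components plus
    the active fiber tension.
    """
    if ri <= 0:
        raise SimulationError("inner radius must be > 0")
    r, lam, dR = _sphere_lambdas(ri, geom)
    lam2 = lam * lam
    lam4i = 1.0 / (lam2 * lam2)
    I1 = lam4i + 2.0 * lam2
    # d psi / d invariants (isochoric == total here: J = 1 exactly)
    psi1 = 0.5 * pp.a * np.exp(np.minimum(pp.b * (I1 - 3.0), 120.0))
    e4 = lam2 - 1.0
    tension = e4 > 0.0
    e4p = np.where(tension, e4, 0.0)
    # fiber and sheet reinforcement (I4f = I4s = lam^2 for tangential axes)
    psi4f = np.where(tension, pp.a_f * e4p * np.exp(np.minimum(pp.b_f * e4p * e4p, 120.0)), 0.0)
    psi4s = np.where(tension, pp.a_s * e4p * np.exp(np.minimum(pp.b_s * e4p * e4p, 120.0)), 0.0)
    # sigma_ff + sigma_ss - 2 sigma_rr from tau = 2 F (dpsi/dC) F^T
    integrand = 2.0 * psi1 * (2.0 * lam2 - 2.0 * lam4i) + 2.0 * (psi4f + psi4s) * lam2
    if ap.Tmax > 0.0:
        Eff = 0.5 * (lam2 - 1.0)
        integrand = integrand + active_tension(t, Eff, ap)
    # dr = R0^2 / r^2 dR0  ->  integrand / r dr = integrand * R0^2 / r^3 dR0
    R0, _ = geom.layer_midpoints()
    P_kpa = float(np.sum(integrand * R0 * R0 / (r**3)) * dR)
    return P_kpa * MMHG_PER_KPA


def wall_strain_energy(ri: float, pp: PassiveParams, geom: ChamberGeometry) -> float:
    """Total passive strain energy of the wall (kPa*mm^3) at inner radius ri.

    Independent route for the equilibrium oracle: the passive cavity
    pressure equals dW/dV_cavity.
    """
    R0, dR = geom.layer_midpoints()
    W = 0.0
    for R in R0:
        state = sphere_layer_deformation(ri, float(R), geom)
        psi_dev, psi_vol = passive_strain_energy(state, pp)
        W += (psi_dev + psi_vol) * 4.0 * math.pi * R * R * dR
    return W


# ---------------------------------------------------------------------------
# closed-loop circulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CirculationParams:
    """Lumped (0-D) closed-loop circulation constants.

    Each ventricle fills through an inflow resistance from a venous
    compartment and ejects through a diode valve into a three-element
    Windkessel (characteristic impedance, peripheral resistance, arterial
    compliance).  Systemic outflow charges the systemic venous compartment
    that feeds the right ventricle; pulmonary outflow charges the pulmonary
    venous compartment that feeds the left ventricle.  Resistances in
    mmHg*s/ml, compliances in ml/mmHg, pressures in mmHg, times in s.
    """

    R_mv: float = 0.05   # mitral (LV inflow) resistance
    R_tv: float = 0.05   # tricuspid (RV inflow) resistance
    Z_ao: float = 0.01   # aortic characteristic impedance
    R_sys: float = 0.4   # systemic peripheral resistance
    C_art: float = 10.0  # systemic arterial compliance
    Z_pa: float = 0.03   # pulmonary characteristic impedance
    R_pul: float = 0.15  # pulmonary peripheral resistance
    C_pa: float = 5.0    # pulmonary arterial compliance
    C_sv: float = 40.0   # systemic venous compliance
    C_pv: float = 30.0   # pulmonary venous compliance
    P_art0: float = 70.0
    P_sv0: float = 8.0
    P_pa0: float = 18.0
    P_pv0: float = 15.0
    T_cycle: float = 0.8
    settle_cycles: int = 5  # minimum warm-up; settling continues adaptively

    def __post_init__(self) -> None:
        positive = (
            "R_mv", "R_tv", "Z_ao", "R_sys", "C_art",
            "Z_pa", "R_pul", "C_pa", "C_sv", "C_pv", "T_cycle",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.settle_cycles < 0:
            raise ConfigError("settle_cycles must be >= 0")


@dataclass(frozen=True)
class PVTrace:
    """One reported cardiac cycle for one chamber on a fixed time grid."""

    chamber: str
    t: np.ndarray
    P: np.ndarray
    V: np.ndarray
    volume_drift: float = 0.0  # |V(end) - V(0)| over the reported cycle (ml)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        P = np.asarray(self.P, dtype=float)
        V = np.asarray(self.V, dtype=float)
        if not (len(t) == len(P) == len(V)):
            raise SimulationError("trace arrays must have equal length")
        if np.any(np.diff(t) <= 0) or t[0] != 0.0:
            raise SimulationError("trace times must start at 0 and increase")
        if np.any(V <= 0):
            raise SimulationError("trace volumes must be positive")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "V", V)

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def stroke_volume(self) -> float:
        return float(self.V.max() - self.V.min())


def _ri_from_volume(V_ml: float) -> float:
    return (3.0 * V_ml / ML_PER_MM3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def _passive_fill_volume(spec: ChamberSpec, P_target: float) -> float:
    """Cavity volume (ml) at which the passive chamber carries P_target mmHg."""
    geom = spec.geometry
    if P_target <= 0.0:
        return geom.cavity_volume0

    def f(V: float) -> float:
        return chamber_pressure(_ri_from_volume(V), 0.0, spec.passive,
                                replace(spec.active, Tmax=0.0), geom) - P_target

    lo = geom.cavity_volume0 * 1.0001
    hi = geom.cavity_volume0 * 1.5
    while f(hi) < 0 and hi < geom.cavity_volume0 * 8:
        hi *= 1.3
    return float(brentq(f, lo, hi, xtol=1e-6))


def simulate_cycle(
    lv: ChamberSpec,
    rv: ChamberSpec,
    circ: CirculationParams,
    n_out: int = 401,
    substeps: int = 4,
) -> Tuple[PVTrace, PVTrace]:
    """Integrate the coupled two-chamber circulation; report the final cycle.

    A fixed-step classical Runge–Kutta scheme advances the six-dimensional
    state (two chamber volumes, arterial/venous compartment pressures of
    both circuits) through at least ``settle_cycles`` warm-up cycles —
    continuing until the per-cycle volume drift of both chambers is below
    0.5% of stroke volume — plus one reported cycle; ``substeps`` RK4 steps
    are taken per output interval so the trajectory lands exactly on the
    ``n_out`` output grid and no interpolation is needed.  Activation
    restarts at the beginning of every cycle.
    """
    if n_out < 3:
        raise ConfigError("n_out must be >= 3")
    for spec in (lv, rv):
        tr_est = spec.active.m_relax * spec.active.lR * 1.5 + spec.active.b_relax
        if circ.T_cycle <= spec.active.t0 + max(tr_est, 0.0):
            raise ConfigError("T_cycle must exceed t0 + relaxation duration")

    from . import _fast

    V_lv0 = _passive_fill_volume(lv, circ.P_pv0)
    V_rv0 = _passive_fill_volume(rv, circ.P_sv0)
    y0 = np.array([V_lv0, V_rv0, circ.P_art0, circ.P_sv0, circ.P_pa0, circ.P_pv0])

    record_V, status, _n_cycles = _fast.integrate_cycles(
        y0,
        _fast.pack_passive(lv.passive), _fast.pack_active(lv.active),
        _fast.pack_geometry(lv.geometry),
        _fast.pack_passive(rv.passive), _fast.pack_active(rv.active),
        _fast.pack_geometry(rv.geometry),
        _fast.pack_circulation(circ), circ.T_cycle, circ.settle_cycles, n_out,
        120, substeps,
    )
    if status == 1:
        raise IntegrationError("chamber volume became non-positive")
    if status == 2:
        raise IntegrationError("non-finite state during integration")
    t_grid = np.linspace(0.0, circ.T_cycle, n_out)

    traces = []
    for idx, (name, spec) in enumerate((("LV", lv), ("RV", rv))):
        V = record_V[:, idx]
        P = np.array([
            chamber_pressure(_ri_from_volume(v), tg, spec.passive, spec.active, spec.geometry)
            for v, tg in zip(V, t_grid)
        ])
        drift = abs(float(V[-1] - V[0]))
        sv = float(V.max() - V.min())
        if drift > max(0.02 * sv, 0.01 * float(V.mean())):
            raise IntegrationError(
                f"{name} volume drift {drift:.3g} ml exceeds limit-cycle tolerance"
            )
        traces.append(PVTrace(chamber=name, t=t_grid.copy(), P=P, V=V.copy(),
                              volume_drift=drift))
    return traces[0], traces[1]


# ---------------------------------------------------------------------------
# end-diastolic stress on a truncated prolate spheroid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpheroidGeometry:
    """Truncated prolate spheroid endocardial shell.

    ``b0`` is the equatorial (short) endocardial semi-axis, ``c0`` the
    apex-base (long) semi-axis, both mm; the shell is truncated by the base
    plane at ``z = base_frac * c0`` (apex at ``z = -c0``) and an apical cap
    of ``apex_cut`` rad is excluded.  ``alpha_long`` is the ratio of
    long-axis to short-axis inflation stretch increments; the wall has
    constant thickness ``h`` with ``n_trans`` transmural quadrature layers
    and a linear transmural helix-angle law from ``helix_endo`` to
    ``helix_epi``.
    """

    b0: float = 20.0
    c0: float = 45.0
    base_frac: float = 0.3
    apex_cut: float = 0.25
    h: float = 10.0
    alpha_long: float = 0.4
    helix_endo: float = math.radians(60.0)
    helix_epi: float = math.radians(-60.0)
    #: apex-to-base variation of the endocardial helix angle (rad); the
    #: angle runs from helix_endo + gradient/2 at the apical edge to
    #: helix_endo - gradient/2 at the base, emulating the apexward
    #: steepening of fiber pitch seen in histology
    helix_endo_gradient: float = 0.0
    n_theta: int = 24
    n_phi: int = 24
    n_trans: int = 3

    def __post_init__(self) -> None:
        if self.b0 <= 0 or self.c0 <= 0 or self.h <= 0:
            raise ConfigError("semi-axes and thickness must be > 0")
        if not -1.0 < self.base_frac < 1.0:
            raise ConfigError("base_frac must lie in (-1, 1)")
        if self.n_theta < 2 or self.n_phi < 2 or self.n_trans < 1:
            raise ConfigError("grid sizes must be >= 2 (>= 1 transmural)")
        phi_base = math.acos(-self.base_frac)
        if not 0.0 < self.apex_cut < phi_base:
            raise ConfigError("apex_cut must lie strictly below the base angle")

    @property
    def phi_base(self) -> float:
        return math.acos(-self.base_frac)

    @property
    def n_elements(self) -> int:
        return self.n_theta * self.n_phi


@dataclass(frozen=True)
class EDMesh:
    """Endocardial element centroids of the spheroid shell (reference state)."""

    geometry: SpheroidGeometry
    element_id: np.ndarray   # (n,)
    phi: np.ndarray          # polar parameter from the apex (rad)
    theta: np.ndarray        # circumferential coordinate (rad)
    area_weight: np.ndarray  # reference surface area per element (mm^2)
    helix_endo: np.ndarray   # fiber helix angle at the endocardium (rad)

    @property
    def n_elements(self) -> int:
        return len(self.element_id)

    @property
    def r(self) -> np.ndarray:
        """Reference cylindrical radius of each centroid (mm)."""
        return self.geometry.b0 * np.sin(self.phi)

    @property
    def z(self) -> np.ndarray:
        """Reference longitudinal coordinate (mm), apex at -c0."""
        return -self.geometry.c0 * np.cos(self.phi)


@dataclass(frozen=True)
class StressRecord:
    """End-diastolic stresses at one endocardial centroid (deformed coords)."""

    element_id: int
    r: float
    theta: float
    z: float
    S11: float
    S22: float
    S12: float


def build_ed_mesh(geom: SpheroidGeometry) -> EDMesh:
    """Grid the truncated spheroid endocardium into element centroids.

    ``n_phi`` equal polar bins between the apical cut and the base plane
    crossed with ``n_theta`` equispaced circumferential stations; centroids
    at bin centers.  Deterministic given the geometry.
    """
    dphi = (geom.phi_base - geom.apex_cut) / geom.n_phi
    dtheta = 2.0 * math.pi / geom.n_theta
    phi_c = geom.apex_cut + (np.arange(geom.n_phi) + 0.5) * dphi
    theta_c = (np.arange(geom.n_theta) + 0.5) * dtheta
    phi_grid, theta_grid = np.meshgrid(phi_c, theta_c, indexing="ij")
    phi_flat = phi_grid.ravel()
    theta_flat = theta_grid.ravel()
    # reference surface area element of the spheroid
    meridian = np.sqrt(
        geom.b0**2 * np.cos(phi_flat) ** 2 + geom.c0**2 * np.sin(phi_flat) ** 2
    )
    area = geom.b0 * np.sin(phi_flat) * meridian * dphi * dtheta
    s = (phi_flat - 0.5 * (geom.apex_cut + geom.phi_base)) / (geom.phi_base - geom.apex_cut)
    helix = geom.helix_endo - geom.helix_endo_gradient * s
    return EDMesh(
        geometry=geom,
        element_id=np.arange(phi_flat.size),
        phi=phi_flat,
        theta=theta_flat,
        area_weight=area,
        helix_endo=helix,
    )


def _inflation_stretches(mesh: EDMesh, kappa: float) -> Tuple[np.ndarray, np.ndarray]:
    """In-surface stretches (circumferential, longitudinal) at inflation kappa."""
    g = mesh.geometry
    lam_c = np.full(mesh.n_elements, 1.0 + kappa)
    b1 = g.b0 * (1.0 + kappa)
    c1 = g.c0 * (1.0 + g.alpha_long * kappa)
    num = np.sqrt(b1**2 * np.cos(mesh.phi) ** 2 + c1**2 * np.sin(mesh.phi) ** 2)
    den = np.sqrt(g.b0**2 * np.cos(mesh.phi) ** 2 + g.c0**2 * np.sin(mesh.phi) ** 2)
    return lam_c, num / den


def _shell_energy_density(
    lam_c: np.ndarray, lam_l: np.ndarray, helix: np.ndarray, pp: PassiveParams
) -> np.ndarray:
    """Deviatoric energy density (kPa) of the incompressible shell point.

    Local F = diag(lam_c, lam_l, 1/(lam_c*lam_l)) in the (circumferential,
    longitudinal, radial) frame, fiber/sheet rotated by the helix angle in
    the tangent plane; J = 1 so the invariants need no isochoric split.
    """
    lc2, ll2 = lam_c**2, lam_l**2
    lr2 = 1.0 / (lc2 * ll2)
    cg, sg = np.cos(helix), np.sin(helix)
    I1 = lc2 + ll2 + lr2
    I4f = lc2 * cg**2 + ll2 * sg**2
    I4s = lc2 * sg**2 + ll2 * cg**2
    I8 = (ll2 - lc2) * sg * cg
    psi = pp.a / (2 * pp.b) * np.exp(pp.b * (I1 - 3.0))
    e4f = np.where(I4f > 1.0, I4f - 1.0, 0.0)
    psi = psi + pp.a_f / (2 * pp.b_f) * np.expm1(pp.b_f * e4f**2)
    e4s = np.where(I4s > 1.0, I4s - 1.0, 0.0)
    psi = psi + pp.a_s / (2 * pp.b_s) * np.expm1(pp.b_s * e4s**2)
    psi = psi + pp.a_fs / (2 * pp.b_fs) * np.expm1(pp.b_fs * I8**2)
    return psi


def _shell_energy(mesh: EDMesh, pp: PassiveParams, kappa: float) -> float:
    """Total passive energy (kPa*mm^3) over surface x transmural quadrature."""
    g = mesh.geometry
    lam_c, lam_l = _inflation_stretches(mesh, kappa)
    W = 0.0
    for k in range(g.n_trans):
        depth = (k + 0.5) / g.n_trans
        helix = mesh.helix_endo + depth * (g.helix_epi - g.helix_endo)
        psi = _shell_energy_density(lam_c, lam_l, helix, pp)
        W += float(np.sum(psi * mesh.area_weight)) * (g.h / g.n_trans)
    return W


def cavity_volume(geom: SpheroidGeometry, kappa: float) -> float:
    """Cavity volume (ml) enclosed by the deformed endocardium and base plane."""
    b1 = geom.b0 * (1.0 + kappa)
    c1 = geom.c0 * (1.0 + geom.alpha_long * kappa)
    zb = geom.base_frac * geom.c0 * (1.0 + geom.alpha_long * kappa)
    V = math.pi * b1**2 * ((zb + c1) - (zb**3 + c1**3) / (3.0 * c1**2))
    return V * ML_PER_MM3


def _inflation_pressure(mesh: EDMesh, pp: PassiveParams, kappa: float) -> float:
    """Equilibrium pressure (mmHg) at inflation kappa: dW/dkappa / dV/dkappa."""
    d = 1.0e-5 * (1.0 + kappa)
    dW = (_shell_energy(mesh, pp, kappa + d) - _shell_energy(mesh, pp, kappa - d)) / (2 * d)
    dV = (cavity_volume(mesh.geometry, kappa + d) - cavity_volume(mesh.geometry, kappa - d)) / (2 * d)
    return dW * ML_PER_MM3 / dV * MMHG_PER_KPA


def ed_inflation_solve(
    pp: PassiveParams,
    PED: float,
    mesh: EDMesh,
    kappa_max: float = 3.0,
    tol_mmHg: float = 0.01,
) -> float:
    """Solve the global inflation scalar kappa for end-diastolic pressure PED.

    Finds the root of ``dW/dkappa = PED * dV/dkappa`` by bracketed root
    finding; ``kappa = 0`` for an unloaded ventricle.  Raises
    :class:`SimulationError` when the wall is too stiff/soft to reach PED
    within ``kappa_max``.
    """
    if PED < 0:
        raise ConfigError("PED must be >= 0")
    if PED == 0.0:
        return 0.0
    f = lambda k: _inflation_pressure(mesh, pp, k) - PED
    lo = 1.0e-8
    if f(lo) >= 0.0:  # pragma: no cover - degenerate, PED below numeric floor
        return lo
    hi = 0.05
    while f(hi) < 0.0:
        hi *= 1.6
        if hi > kappa_max:
            raise SimulationError(
                f"no inflation bracket in kappa <= {kappa_max}: wall too soft "
                f"or pressure {PED} mmHg unreachable"
            )
    kappa = float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))
    if abs(_inflation_pressure(mesh, pp, kappa) - PED) > tol_mmHg:
        raise SimulationError("inflation solve did not meet pressure tolerance")
    return kappa


def tangent_stress_components(
    lam_c: float,
    lam_l: float,
    helix: float,
    pp: PassiveParams,
    endo_pressure_kpa: float = 0.0,
) -> Tuple[float, float, float]:
    """Fiber, cross-fiber and shear Cauchy stresses (kPa) at a shell point.

    The local deformation is exactly isochoric, so the constitutive law
    determines the stress only up to a hydrostatic reaction pressure; that
    pressure is fixed by the endocardial traction boundary condition
    ``sigma_rr = -P_ED`` at the inner surface.  The resulting total stress
    is projected on the deformed fiber/sheet directions:
    S11 = f.sigma.f, S22 = s.sigma.s, S12 = f.sigma.s.
    """
    F = np.diag([lam_c, lam_l, 1.0 / (lam_c * lam_l)])
    cg, sg = math.cos(helix), math.sin(helix)
    f0 = np.array([cg, sg, 0.0])
    s0 = np.array([-sg, cg, 0.0])
    state = DeformationState(F=F, f0=f0, s0=s0)
    sigma = passive_cauchy_stress(state, pp)
    p_reaction = -endo_pressure_kpa - sigma[2, 2]  # radial = 3rd local axis
    sigma = sigma + p_reaction * np.eye(3)
    fhat = F @ f0
    fhat /= np.linalg.norm(fhat)
    shat = F @ s0
    shat /= np.linalg.norm(shat)
    return (
        float(fhat @ sigma @ fhat),
        float(shat @ sigma @ shat),
        float(fhat @ sigma @ shat),
    )


def ed_stress_field(
    pp: PassiveParams, PED: float, mesh: EDMesh
) -> List[StressRecord]:
    """Passive end-diastolic stresses at every endocardial centroid.

    Solves the inflation scalar for ``PED``, then evaluates the local
    deformation (helix-angle fiber frame at the endocardium) with the
    hydrostatic reaction pressure anchored to the endocardial traction,
    and reports S11/S22/S12 with centroid coordinates in the deformed
    configuration.
    """
    g = mesh.geometry
    kappa = ed_inflation_solve(pp, PED, mesh)
    lam_c, lam_l = _inflation_stretches(mesh, kappa)
    b1 = g.b0 * (1.0 + kappa)
    c1 = g.c0 * (1.0 + g.alpha_long * kappa)
    ped_kpa = PED * KPA_PER_MMHG
    records = []
    for i in range(mesh.n_elements):
        s11, s22, s12 = tangent_stress_components(
            float(lam_c[i]), float(lam_l[i]), float(mesh.helix_endo[i]), pp,
            endo_pressure_kpa=ped_kpa,
        )
        records.append(
            StressRecord(
                element_id=int(mesh.element_id[i]),
                r=float(b1 * math.sin(mesh.phi[i])),
                theta=float(mesh.theta[i]),
                z=float(-c1 * math.cos(mesh.phi[i])),
                S11=s11,
                S22=s22,
                S12=s12,
            )
        )
    return records


# ---------------------------------------------------------------------------
# dataset generators
# ---------------------------------------------------------------------------


def _split_ids(n: int, n_test: int, seed: int) -> Tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    test = np.sort(rng.choice(n, size=n_test, replace=False))
    train = np.setdiff1d(np.arange(n), test)
    return train, test


def generate_pv_dataset(
    plan,
    lv: ChamberSpec,
    rv: ChamberSpec,
    circ: CirculationParams,
    n_train: int = 77,
    n_test: int = 3,
    seed: int = 0,
    n_out: int = 401,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cardiac cycle per DOE sample and split by whole cycles.

    ``plan`` must provide the six active features ``l0_LV, l0_RV, t0_LV,
    t0_RV, Tmax_LV, Tmax_RV`` (um, s, kPa) for ``n_train + n_test``
    samples.  Each cycle contributes ``n_out`` rows of
    ``(features, t) -> (P_LV, V_LV)``; test cycles never appear in the
    training table.  Any non-converged sample aborts the run.
    """
    table = plan.to_dataframe() if hasattr(plan, "to_dataframe") else pd.DataFrame(plan)
    missing = [c for c in PV_FEATURES[:-1] if c not in table.columns]
    if missing:
        raise ConfigError(f"DOE plan lacks feature columns: {missing}")
    if len(table) != n_train + n_test:
        raise ConfigError(
            f"plan has {len(table)} samples, expected {n_train + n_test}"
        )
    frames = []
    failures = []
    for cycle_id, row in table.iterrows():
        ap_lv = replace(lv.active, l0=row["l0_LV"], t0=row["t0_LV"], Tmax=row["Tmax_LV"])
        ap_rv = replace(rv.active, l0=row["l0_RV"], t0=row["t0_RV"], Tmax=row["Tmax_RV"])
        try:
            trace_lv, _ = simulate_cycle(
                replace(lv, active=ap_lv), replace(rv, active=ap_rv), circ, n_out=n_out
            )
        except (SimulationError, ConstitutiveError) as exc:
            failures.append((int(cycle_id), str(exc)))
            continue
        frame = pd.DataFrame({
            "cycle_id": int(cycle_id),
            "l0_LV": row["l0_LV"], "l0_RV": row["l0_RV"],
            "t0_LV": row["t0_LV"], "t0_RV": row["t0_RV"],
            "Tmax_LV": row["Tmax_LV"], "Tmax_RV": row["Tmax_RV"],
            "t": trace_lv.t, "P_LV": trace_lv.P, "V_LV": trace_lv.V,
        })
        frames.append(frame)
    if failures:
        raise SimulationError(
            "cycle simulations failed (all samples must converge): "
            + "; ".join(f"sample {i}: {msg}" for i, msg in failures)
        )
    data = pd.concat(frames, ignore_index=True)
    train_ids, test_ids = _split_ids(len(table), n_test, seed)
    train = data[data["cycle_id"].isin(train_ids)].reset_index(drop=True)
    test = data[data["cycle_id"].isin(test_ids)].reset_index(drop=True)
    return train, test


def generate_stress_dataset(
    plan,
    geom: SpheroidGeometry,
    n_train: int = 100,
    n_test: int = 20,
    seed: int = 0,
    PED: float = 16.38,
    base_passive: Optional[PassiveParams] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """End-diastolic stress fields for a passive-parameter DOE, split by model.

    ``plan`` provides ``a, a_s, a_f, a_fs`` in MPa (the feature scale of the
    datasets); internally they are converted to kPa and combined with the
    fixed exponent constants of ``base_passive`` (package defaults when
    omitted).  Each model contributes one row per endocardial element with
    deformed centroid coordinates and S11/S22/S12 in kPa.
    """
    table = plan.to_dataframe() if hasattr(plan, "to_dataframe") else pd.DataFrame(plan)
    missing = [c for c in ("a", "a_s", "a_f", "a_fs") if c not in table.columns]
    if missing:
        raise ConfigError(f"DOE plan lacks feature columns: {missing}")
    if len(table) != n_train + n_test:
        raise ConfigError(
            f"plan has {len(table)} samples, expected {n_train + n_test}"
        )
    base = base_passive if base_passive is not None else PassiveParams()
    mesh = build_ed_mesh(geom)
    frames = []
    failures = []
    for model_id, row in table.iterrows():
        pp = replace(
            base,
            a=row["a"] * 1000.0,
            a_s=row["a_s"] * 1000.0,
            a_f=row["a_f"] * 1000.0,
            a_fs=row["a_fs"] * 1000.0,
        )
        try:
            records = ed_stress_field(pp, PED, mesh)
        except (SimulationError, ConstitutiveError) as exc:
            failures.append((int(model_id), str(exc)))
            continue
        frame = pd.DataFrame({
            "model_id": int(model_id),
            "element_id": [rec.element_id for rec in records],
            "a": row["a"], "a_s": row["a_s"],
            "a_f": row["a_f"], "a_fs": row["a_fs"],
            "r": [rec.r for rec in records],
            "theta": [rec.theta for rec in records],
            "z": [rec.z for rec in records],
            "S11": [rec.S11 for rec in records],
            "S22": [rec.S22 for rec in records],
            "S12": [rec.S12 for rec in records],
        })
        frames.append(frame)
    if failures:
        raise SimulationError(
            "stress-field computations failed (all samples must converge): "
            + "; ".join(f"model {i}: {msg}" for i, msg in failures)
        )
    data = pd.concat(frames, ignore_index=True)
    train_ids, test_ids = _split_ids(len(table), n_test, seed)
    train = data[data["model_id"].isin(train_ids)].reset_index(drop=True)
    test = data[data["model_id"].isin(test_ids)].reset_index(drop=True)
    return train, test
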