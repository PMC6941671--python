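"""Numba kernels for the closed-loop chamber-circulation integrator.

The inner Runge-Kutta loop evaluates the thick-walled-sphere cavity
pressure thousands of times per cycle; these kernels replicate the
material-point formulas of :mod:`ventriq.constitutive` in scalar form so
the whole integration runs compiled.  Consistency with the reference
implementation is enforced by tests (`chamber_pressure` vs the kernel on
random states).

Parameter packing (see :func:`pack_chamber`):
passive  [a, b, a_f, b_f, a_s, b_s]          (shear/volumetric terms drop
                                              out of the pressure integral)
active   [Tmax, Ca0, Ca0max, B, l0, lR, t0, m_relax, b_relax]
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

MMHG_PER_KPA = 7.500616827041698  # 1/0.1333223684

_EXP_CAP = 120.0


@njit(cache=False)
def _active_T0(t: float, lam: float, ap: np.ndarray) -> float:
    Tmax, Ca0, Ca0max, B, l0, lR, t0, m, b = (
        ap[0], ap[1], ap[2], ap[3], ap[4], ap[5], ap[6], ap[7], ap[8])
    l = lR * lam
    if l <= l0 or Tmax <= 0.0:
        return 0.0
    tr = m * l + b
    if tr <= 0.0:
        return 0.0
    if t <= t0:
        w = math.pi * t / t0
    elif t <= t0 + tr:
        w = math.pi * (t - t0 + tr) / tr
    else:
        return 0.0
    ct = 0.5 * (1.0 - math.cos(w))
    e50sq = Ca0max * Ca0max / math.expm1(B * (l - l0))
    return Tmax * Ca0 * Ca0 / (Ca0 * Ca0 + e50sq) * ct


@njit(cache=False)
def chamber_pressure_fast(
    ri: float, t: float, pp: np.ndarray, ap: np.ndarray,
    Ri: float, Ro: float, n_layers: int,
) -> float:
    """Cavity pressure (mmHg): midpoint quadrature of the equilibrium integral."""
    a, b, a_f, b_f, a_s, b_s = pp[0], pp[1], pp[2], pp[3], pp[4], pp[5]
    dR = (Ro - Ri) / n_layers
    ri3 = ri * ri * ri
    Ri3 = Ri * Ri * Ri
    P = 0.0
    for k in range(n_layers):
        R0 = Ri + (k + 0.5) * dR
        R03 = R0 * R0 * R0
        r3 = ri3 + R03 - Ri3
        r = r3 ** (1.0 / 3.0)
        lam = r / R0
        lam2 = lam * lam
        lam4i = 1.0 / (lam2 * lam2)
        arg = b * (lam4i + 2.0 * lam2 - 3.0)
        if arg > _EXP_CAP:
            arg = _EXP_CAP
        psi1 = 0.5 * a * math.exp(arg)
        integ = 2.0 * psi1 * (2.0 * lam2 - 2.0 * lam4i)
        e4 = lam2 - 1.0
        if e4 > 0.0:
            argf = b_f * e4 * e4
            if argf > _EXP_CAP:
                argf = _EXP_CAP
            args = b_s * e4 * e4
            if args > _EXP_CAP:
                args = _EXP_CAP
            integ += 2.0 * (a_f * e4 * math.exp(argf)
                            + a_s * e4 * math.exp(args)) * lam2
        integ += _active_T0(t, lam, ap)
        P += integ * R0 * R0 / r3 * dR
    return P * MMHG_PER_KPA


@njit(cache=False)
def _rhs(
    tc: float, y: np.ndarray, out: np.ndarray,
    pp_lv: np.ndarray, ap_lv: np.ndarray, geo_lv: np.ndarray,
    pp_rv: np.ndarray, ap_rv: np.ndarray, geo_rv: np.ndarray,
    circ: np.ndarray,
) -> int:
    V_lv, V_rv = y[0], y[1]
    P_art, P_sv, P_pa, P_pv = y[2], y[3], y[4], y[5]
    if V_lv <= 0.0 or V_rv <= 0.0:
        return 1
    c = 3.0 / (4.0 * math.pi) * 1000.0  # ml -> mm^3 radius factor
    ri_lv = (c * V_lv) ** (1.0 / 3.0)
    ri_rv = (c * V_rv) ** (1.0 / 3.0)
    P_LV = chamber_pressure_fast(ri_lv, tc, pp_lv, ap_lv,
                                 geo_lv[0], geo_lv[1], int(geo_lv[2]))
    P_RV = chamber_pressure_fast(ri_rv, tc, pp_rv, ap_rv,
                                 geo_rv[0], geo_rv[1], int(geo_rv[2]))
    R_mv, R_tv, Z_ao, R_sys, C_art, Z_pa, R_pul, C_pa, C_sv, C_pv = (
        circ[0], circ[1], circ[2], circ[3], circ[4],
        circ[5], circ[6], circ[7], circ[8], circ[9])
    q_mv = (P_pv - P_LV) / R_mv
    if q_mv < 0.0:
        q_mv = 0.0
    q_av = (P_LV - P_art) / Z_ao
    if q_av < 0.0:
        q_av = 0.0
    q_tv = (P_sv - P_RV) / R_tv
    if q_tv < 0.0:
        q_tv = 0.0
    q_pa = (P_RV - P_pa) / Z_pa
    if q_pa < 0.0:
        q_pa = 0.0
    out[0] = q_mv - q_av
    out[1] = q_tv - q_pa
    out[2] = (q_av - (P_art - P_sv) / R_sys) / C_art
    out[3] = ((P_art - P_sv) / R_sys - q_tv) / C_sv
    out[4] = (q_pa - (P_pa - P_pv) / R_pul) / C_pa
    out[5] = ((P_pa - P_pv) / R_pul - q_mv) / C_pv
    return 0


@njit(cache=False)
def _one_cycle(
    y: np.ndarray, record: np.ndarray, recording: bool,
    pp_lv: np.ndarray, ap_lv: np.ndarray, geo_lv: np.ndarray,
    pp_rv: np.ndarray, ap_rv: np.ndarray, geo_rv: np.ndarray,
    circ: np.ndarray, dt: float, n_steps: int, substeps: int,
):
    """Advance one cardiac cycle in place; returns (status, sv_lv, sv_rv)."""
    k1 = np.empty(6); k2 = np.empty(6); k3 = np.empty(6); k4 = np.empty(6)
    yt = np.empty(6)
    vmin_lv = y[0]; vmax_lv = y[0]
    vmin_rv = y[1]; vmax_rv = y[1]
    if recording:
        record[0, 0] = y[0]
        record[0, 1] = y[1]
    for step in range(n_steps):
        tc = step * dt
        if _rhs(tc, y, k1, pp_lv, ap_lv, geo_lv, pp_rv, ap_rv, geo_rv, circ):
            return 1, 0.0, 0.0
        for i in range(6):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        if _rhs(tc + 0.5 * dt, yt, k2, pp_lv, ap_lv, geo_lv, pp_rv, ap_rv, geo_rv, circ):
            return 1, 0.0, 0.0
        for i in range(6):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        if _rhs(tc + 0.5 * dt, yt, k3, pp_lv, ap_lv, geo_lv, pp_rv, ap_rv, geo_rv, circ):
            return 1, 0.0, 0.0
        for i in range(6):
            yt[i] = y[i] + dt * k3[i]
        if _rhs(tc + dt, yt, k4, pp_lv, ap_lv, geo_lv, pp_rv, ap_rv, geo_rv, circ):
            return 1, 0.0, 0.0
        for i in range(6):
            y[i] = y[i] + dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if not math.isfinite(y[i]):
                return 2, 0.0, 0.0
        if y[0] < vmin_lv: vmin_lv = y[0]
        if y[0] > vmax_lv: vmax_lv = y[0]
        if y[1] < vmin_rv: vmin_rv = y[1]
        if y[1] > vmax_rv: vmax_rv = y[1]
        if recording and (step + 1) % substeps == 0:
            idx = (step + 1) // substeps
            record[idx, 0] = y[0]
            record[idx, 1] = y[1]
    return 0, vmax_lv - vmin_lv, vmax_rv - vmin_rv


@njit(cache=False)
def integrate_cycles(
    y0: np.ndarray,
    pp_lv: np.ndarray, ap_lv: np.ndarray, geo_lv: np.ndarray,
    pp_rv: np.ndarray, ap_rv: np.ndarray, geo_rv: np.ndarray,
    circ: np.ndarray, T_cycle: float, settle_cycles: int, n_out: int,
    max_cycles: int = 120, substeps: int = 2,
):
    """Fixed-step RK4 to a periodic limit cycle; record the final cycle.

    Runs at least ``settle_cycles`` warm-up cycles, then keeps cycling until
    the per-cycle volume drift of both chambers falls below 0.5% of that
    chamber's stroke volume (floored at 0.02 ml for quiescent chambers) or
    ``max_cycles`` is reached, and finally records one more cycle on the
    ``n_out`` output grid.  Returns (record_V[n_out, 2], status, n_cycles);
    status 0 on success, 1 on a collapsed chamber, 2 on a non-finite state.
    """
    n_steps = substeps * (n_out - 1)
    dt = T_cycle / n_steps
    y = y0.copy()
    record = np.zeros((n_out, 2))
    cycles = 0
    while cycles < max_cycles:
        v_lv0 = y[0]; v_rv0 = y[1]
        status, sv_lv, sv_rv = _one_cycle(
            y, record, False, pp_lv, ap_lv, geo_lv, pp_rv, ap_rv, geo_rv,
            circ, dt, n_steps, substeps)
        cycles += 1
        if status != 0:
            return record, status, cycles
        if cycles >= settle_cycles:
            tol_lv = max(0.005 * sv_lv, 0.02)
            tol_rv = max(0.005 * sv_rv, 0.02)
            if abs(y[0] - v_lv0) < tol_lv and abs(y[1] - v_rv0) < tol_rv:
                break
    status, _, _ = _one_cycle(
        y, record, True, pp_lv, ap_lv, geo_lv, pp_rv, ap_rv, geo_rv,
        circ, dt, n_steps, substeps)
    return record, status, cycles + 1


def pack_passive(pp) -> np.ndarray:
    return np.array([pp.a, pp.b, pp.a_f, pp.b_f, pp.a_s, pp.b_s], dtype=float)


def pack_active(ap) -> np.ndarray:
    return np.array([ap.Tmax, ap.Ca0, ap.Ca0max, ap.B, ap.l0, ap.lR,
                     ap.t0, ap.m_relax, ap.b_relax], dtype=float)


def pack_geometry(geom) -> np.ndarray:
    return np.array([geom.Ri, geom.Ro, float(geom.n_layers)], dtype=float)


def pack_circulation(circ) -> np.ndarray:
    return np.array([circ.R_mv, circ.R_tv, circ.Z_ao, circ.R_sys, circ.C_art,
                     circ.Z_pa, circ.R_pul, circ.C_pa, circ.C_sv, circ.C_pv],
                    dtype=float)
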