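"""Material-point checks: invariants, energies, stresses, activation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import fd_cauchy_stress, random_incompressible_state, random_passive_params
from ventriq.constitutive import (
    ActiveParams,
    ConstitutiveError,
    DeformationState,
    InvalidDeformationError,
    InvalidParameterError,
    InvalidStrainError,
    PassiveParams,
    SaturationError,
    active_tension,
    ct_waveform,
    eca50,
    fiber_strain,
    invariants,
    passive_cauchy_stress,
    passive_strain_energy,
    relaxation_duration,
    sarcomere_length,
    total_cauchy_stress,
)

E1, E2, E3 = np.eye(3)


class TestInvariants:
    def test_identity_reference(self):
        inv = invariants(DeformationState(F=np.eye(3), f0=E1, s0=E2))
        assert (inv.I1, inv.I4f, inv.I4s, inv.I8fs) == (3.0, 1.0, 1.0, 0.0)

    def test_uniaxial_fiber_stretch(self):
        F = np.diag([2.0, 2 ** -0.5, 2 ** -0.5])
        state = DeformationState(F=F, f0=E1, s0=E2)
        inv = invariants(state)
        assert state.J == pytest.approx(1.0)
        assert inv.I4f == pytest.approx(4.0)

    def test_simple_shear(self):
        # F = I + 0.5 e1(x)e2: C = [[1,.5,0],[.5,1.25,0],[0,0,1]]
        F = np.eye(3)
        F[0, 1] = 0.5
        inv = invariants(DeformationState(F=F, f0=E1, s0=E2))
        assert inv.I1 == pytest.approx(3.25)
        assert inv.I4f == pytest.approx(1.0)
        assert inv.I4s == pytest.approx(1.25)
        assert inv.I8fs == pytest.approx(0.5)

    def test_isochoric_invariants_ignore_volume_change(self):
        state = DeformationState(F=1.3 * np.eye(3), f0=E1, s0=E2)
        inv = invariants(state)
        assert inv.I1 == pytest.approx(3.0)
        assert inv.I4f == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [np.full((3, 3), np.nan), -np.eye(3), np.zeros((3, 3))])
    def test_invalid_deformations_rejected(self, bad):
        with pytest.raises(InvalidDeformationError):
            DeformationState(F=bad, f0=E1, s0=E2)

    def test_nonorthogonal_directions_rejected(self):
        with pytest.raises(InvalidDeformationError):
            DeformationState(F=np.eye(3), f0=E1, s0=(E1 + E2) / math.sqrt(2))


class TestPassiveEnergy:
    def test_reference_energy_is_isotropic_floor(self, passive):
        psi_dev, psi_vol = passive_strain_energy(
            DeformationState(F=np.eye(3), f0=E1, s0=E2), passive
        )
        assert psi_dev == pytest.approx(passive.a / (2 * passive.b))
        assert psi_vol == 0.0

    def test_volumetric_energy_vanishes_when_isochoric(self, rng, passive):
        state = random_incompressible_state(rng)
        _, psi_vol = passive_strain_energy(state, passive)
        assert psi_vol == pytest.approx(0.0, abs=1e-9)

    def test_zero_fiber_coefficient_removes_fiber_term(self, rng):
        state = random_incompressible_state(rng)
        p0 = random_passive_params(rng)
        p1 = PassiveParams(**{**p0.to_dict(), "a_f": 0.0})
        p2 = PassiveParams(**{**p0.to_dict(), "a_f": 2.0 * p0.a_f})
        w0 = passive_strain_energy(state, p1)[0]
        w2 = passive_strain_energy(state, p2)[0]
        w1 = passive_strain_energy(state, p0)[0]
        # energy is affine in a_f: removing the term and doubling it bracket it
        assert w0 <= w1 + 1e-12
        assert w1 == pytest.approx((w0 + w2) / 2, rel=1e-9)

    def test_overflow_names_offending_term(self):
        state = DeformationState(F=np.diag([30.0, 30 ** -0.5, 30 ** -0.5]), f0=E1, s0=E2)
        with pytest.raises(SaturationError, match="isotropic"):
            passive_strain_energy(state, PassiveParams())


class TestPassiveStress:
    def test_stress_free_reference(self, rng):
        for _ in range(5):
            p = random_passive_params(rng)
            sigma = passive_cauchy_stress(DeformationState(F=np.eye(3), f0=E1, s0=E2), p)
            assert np.allclose(sigma, 0.0, atol=1e-12)

    def test_matches_energy_oracle(self, rng):
        for _ in range(25):
            state = random_incompressible_state(rng)
            p = random_passive_params(rng)
            sigma = passive_cauchy_stress(state, p)
            sigma_fd = fd_cauchy_stress(state, p)
            scale = max(np.abs(sigma_fd).max(), 1e-8)
            assert np.abs(sigma - sigma_fd).max() / scale < 1e-5

    def test_symmetry(self, rng):
        state = random_incompressible_state(rng)
        sigma = passive_cauchy_stress(state, random_passive_params(rng))
        assert np.allclose(sigma, sigma.T)

    def test_fiber_stress_increases_with_fiber_stiffness(self):
        lam = 1.2
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        state = DeformationState(F=F, f0=E1, s0=E2)
        prev = -np.inf
        for a_f in (0.5, 2.0, 5.0, 20.0):
            sigma = passive_cauchy_stress(state, PassiveParams(a_f=a_f))
            assert sigma[0, 0] > prev
            prev = sigma[0, 0]

    def test_objectivity_under_rotation(self, rng):
        for _ in range(10):
            state = random_incompressible_state(rng)
            p = random_passive_params(rng)
            # random rotation via QR
            Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            if np.linalg.det(Q) < 0:
                Q[:, 0] *= -1
            rotated = DeformationState(F=Q @ state.F, f0=state.f0, s0=state.s0)
            lhs = passive_cauchy_stress(rotated, p)
            rhs = Q @ passive_cauchy_stress(state, p) @ Q.T
            assert np.abs(lhs - rhs).max() < 1e-8


class TestActivation:
    def test_sarcomere_length_cases(self):
        assert sarcomere_length(0.0, 1.85) == pytest.approx(1.85)
        assert sarcomere_length(1.5, 1.85) == pytest.approx(3.70)
        assert sarcomere_length(-0.18, 1.85) == pytest.approx(1.85 * 0.8)

    def test_sarcomere_length_invalid_strain(self):
        with pytest.raises(InvalidStrainError):
            sarcomere_length(-0.6, 1.85)

    def test_relaxation_duration(self, active):
        flat = ActiveParams(m_relax=0.0, b_relax=0.07)
        assert relaxation_duration(1.0, flat) == relaxation_duration(3.0, flat) == 0.07
        slope = ActiveParams(m_relax=0.05, b_relax=1e-12)
        assert relaxation_duration(2.0, slope) == pytest.approx(0.10)
        assert relaxation_duration(1.5, active) < relaxation_duration(2.5, active)

    def test_ct_waveform_landmarks(self):
        t0, tr = 0.15, 0.1
        assert ct_waveform(0.0, t0, tr) == 0.0
        assert ct_waveform(t0, t0, tr) == pytest.approx(1.0)
        assert ct_waveform(t0 + tr / 2, t0, tr) == pytest.approx(0.5)
        assert ct_waveform(t0 + tr, t0, tr) == 0.0
        assert ct_waveform(t0 + 2 * tr, t0, tr) == 0.0

    @given(
        t=st.floats(0.0, 1.0),
        t0=st.floats(0.05, 0.3),
        tr=st.floats(0.02, 0.3),
    )
    def test_ct_waveform_bounded_and_continuous(self, t, t0, tr):
        ct = ct_waveform(t, t0, tr)
        assert 0.0 <= ct <= 1.0
        eps = 1e-9
        assert abs(ct_waveform(t + eps, t0, tr) - ct) < 1e-6

    def test_eca50_algebra(self):
        p = ActiveParams()
        l_half = p.l0 + math.log(2.0) / p.B
        assert eca50(l_half, p) == pytest.approx(p.Ca0max)
        assert eca50(p.l0, p) == math.inf
        assert eca50(p.l0 - 0.1, p) == math.inf
        assert eca50(p.l0 + 0.2, p) > eca50(p.l0 + 0.4, p)

    def test_tension_zero_regimes(self, active):
        # after the twitch ends
        l = active.lR  # Eff = 0
        tr = relaxation_duration(l, active)
        assert active_tension(active.t0 + tr + 0.01, 0.0, active) == 0.0
        # below the zero-tension length
        short = ActiveParams(l0=2.5, lR=1.85)
        assert active_tension(short.t0, 0.0, short) == 0.0

    def test_half_maximal_tension_at_matched_calcium(self):
        p = ActiveParams(Ca0=4.35, Ca0max=4.35)
        l_half = p.l0 + math.log(2.0) / p.B
        Eff = ((l_half / p.lR) ** 2 - 1.0) / 2.0
        assert active_tension(p.t0, Eff, p) == pytest.approx(p.Tmax / 2.0, rel=1e-9)

    def test_tension_bounded_and_monotone_in_length(self, active):
        ts = np.linspace(0.01, active.t0, 7)
        lams = np.linspace(0.9, 1.25, 12)
        Effs = (lams**2 - 1.0) / 2.0
        for t in ts:
            T = active_tension(t, Effs, active)
            assert np.all(T <= active.Tmax + 1e-12)
            assert np.all(np.diff(T) >= -1e-12)

    def test_negative_time_rejected(self, active):
        with pytest.raises(ConstitutiveError):
            active_tension(-0.1, 0.0, active)


class TestTotalStress:
    def test_reduces_to_passive_when_inactive(self, rng, passive, active):
        state = random_incompressible_state(rng)
        tr_max = relaxation_duration(3.5, active)
        sigma = total_cauchy_stress(state, active.t0 + tr_max + 0.5, passive, active)
        assert np.allclose(sigma, passive_cauchy_stress(state, passive))

    def test_unloaded_inactive_reference_is_stress_free(self, passive):
        short = ActiveParams(l0=2.0, lR=1.85)  # l = lR <= l0 at F = I
        sigma = total_cauchy_stress(
            DeformationState(F=np.eye(3), f0=E1, s0=E2), short.t0, passive, short
        )
        assert np.allclose(sigma, 0.0, atol=1e-12)

    def test_active_part_is_rank_one_along_deformed_fiber(self, rng, passive):
        ap = ActiveParams(l0=1.58, lR=1.85)
        state = random_incompressible_state(rng)
        if fiber_strain(state) < 0.02:  # ensure tension is on
            F = state.F @ (np.eye(3) + 0.15 * np.outer(state.f0, state.f0))
            state = DeformationState(F=F, f0=state.f0, s0=state.s0)
        delta = total_cauchy_stress(state, ap.t0, passive, ap) - passive_cauchy_stress(
            state, passive
        )
        w, v = np.linalg.eigh(delta)
        T0 = active_tension(ap.t0, fiber_strain(state), ap)
        assert T0 > 0
        assert w[-1] == pytest.approx(T0, rel=1e-9)
        assert np.abs(w[:-1]).max() < 1e-9 * T0
        fhat = state.F @ state.f0
        fhat /= np.linalg.norm(fhat)
        assert abs(abs(v[:, -1] @ fhat) - 1.0) < 1e-9


class TestParameterValidation:
    def test_passive_param_bounds(self):
        with pytest.raises(InvalidParameterError):
            PassiveParams(a=-1.0)
        with pytest.raises(InvalidParameterError):
            PassiveParams(b=0.0)
        with pytest.raises(InvalidParameterError):
            PassiveParams(D=0.0)

    def test_active_param_bounds(self):
        with pytest.raises(InvalidParameterError):
            ActiveParams(Tmax=-1.0)
        with pytest.raises(InvalidParameterError):
            ActiveParams(t0=0.0)
        with pytest.raises(InvalidParameterError):
            ActiveParams(m_relax=0.0, b_relax=0.0)

    def test_param_dict_round_trip(self):
        p = PassiveParams(a=1.23, a_f=4.56)
        assert PassiveParams.from_dict(p.to_dict()) == p
        a = ActiveParams(Tmax=99.0, l0=1.7)
        assert ActiveParams.from_dict(a.to_dict()) == a


class TestActivationState:
    def test_snapshot_consistent_with_tension_pipeline(self):
        from ventriq.constitutive import activation_state

        p = ActiveParams(l0=1.58, lR=1.85)
        Eff = 0.15
        state = activation_state(p.t0 / 2, Eff, p)
        assert state.l == pytest.approx(sarcomere_length(Eff, p.lR))
        assert state.tr == pytest.approx(relaxation_duration(state.l, p))
        assert state.Ct == pytest.approx(ct_waveform(p.t0 / 2, p.t0, state.tr))
        assert state.ECa50 == pytest.approx(eca50(state.l, p))
        assert state.T0 == pytest.approx(active_tension(p.t0 / 2, Eff, p))
        assert 0.0 <= state.Ct <= 1.0 and 0.0 <= state.T0 <= p.Tmax
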