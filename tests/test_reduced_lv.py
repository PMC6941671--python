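"""Reduced-order simulator: sphere equilibrium, circulation, ED stress fields."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from ventriq import _fast
from ventriq.config import paper2019
from ventriq.constitutive import ActiveParams, MMHG_PER_KPA, PassiveParams
from ventriq.doe import ParameterRanges, latin_hypercube
from ventriq import reduced_lv as rl


@pytest.fixture(scope="module")
def cfg():
    return paper2019()


@pytest.fixture(scope="module")
def lv(cfg):
    return cfg.lv_spec()


@pytest.fixture(scope="module")
def rv(cfg):
    return cfg.rv_spec()


@pytest.fixture(scope="module")
def contracting(cfg):
    ap = dataclasses.replace(cfg.pv.active_base, l0=1.9, t0=0.16, Tmax=120.0)
    lv = dataclasses.replace(cfg.lv_spec(), active=ap)
    rv = dataclasses.replace(cfg.rv_spec(), active=ap)
    return lv, rv


@pytest.fixture(scope="module")
def mesh(cfg):
    return rl.build_ed_mesh(cfg.stress.geometry)


class TestSphereKinematics:
    def test_unloaded_state_is_identity(self, lv):
        geom = lv.geometry
        state = rl.sphere_layer_deformation(geom.Ri, geom.Ri + 2.0, geom)
        assert np.allclose(state.F, np.eye(3))

    @pytest.mark.parametrize("ri_factor", [0.8, 1.0, 1.2, 1.5])
    def test_exact_incompressibility(self, lv, ri_factor):
        geom = lv.geometry
        for R0 in np.linspace(geom.Ri, geom.Ro, 4):
            state = rl.sphere_layer_deformation(ri_factor * geom.Ri, R0, geom)
            assert abs(state.J - 1.0) < 1e-12

    def test_thin_wall_volume_doubling_stretch(self):
        geom = rl.ChamberGeometry(Ri=30.0, wall_volume=1e3, n_layers=3)
        ri = 2.0 ** (1.0 / 3.0) * geom.Ri
        R0, _ = geom.layer_midpoints()
        state = rl.sphere_layer_deformation(ri, float(R0[1]), geom)
        lam = state.F[1, 1]
        assert lam == pytest.approx(2.0 ** (1.0 / 3.0), rel=1e-3)


class TestChamberPressure:
    def test_unloaded_passive_pressure_is_zero(self, lv):
        P = lv.geometry.Ri
        assert rl.chamber_pressure(P, 0.0, lv.passive, lv.active, lv.geometry) == pytest.approx(0.0, abs=1e-12)

    def test_matches_energy_derivative(self, rng, lv):
        """Equilibrium oracle: P equals dW/dV_cavity for passive inflation."""
        geom = lv.geometry
        quiet = dataclasses.replace(lv.active, Tmax=0.0)
        for _ in range(8):
            ri = geom.Ri * rng.uniform(1.02, 1.25)
            P = rl.chamber_pressure(ri, 0.0, lv.passive, quiet, geom)
            h = 1e-4
            dW = (rl.wall_strain_energy(ri + h, lv.passive, geom)
                  - rl.wall_strain_energy(ri - h, lv.passive, geom))
            dV = 4.0 / 3.0 * math.pi * ((ri + h) ** 3 - (ri - h) ** 3)
            P_fd = dW / dV * MMHG_PER_KPA
            assert abs(P - P_fd) / abs(P_fd) < 1e-3

    def test_passive_pressure_strictly_increasing_in_radius(self, lv):
        quiet = dataclasses.replace(lv.active, Tmax=0.0)
        ris = np.linspace(lv.geometry.Ri * 1.01, lv.geometry.Ri * 1.3, 10)
        Ps = [rl.chamber_pressure(r, 0.0, lv.passive, quiet, lv.geometry) for r in ris]
        assert np.all(np.diff(Ps) > 0)

    def test_active_tension_raises_pressure(self, lv):
        ap = dataclasses.replace(lv.active, l0=1.9, Tmax=120.0)
        ri = lv.geometry.Ri * 1.1
        assert (rl.chamber_pressure(ri, ap.t0, lv.passive, ap, lv.geometry)
                > rl.chamber_pressure(ri, 0.0, lv.passive, ap, lv.geometry))

    def test_fast_kernel_matches_reference(self, rng, lv):
        """The compiled integrator kernel reproduces chamber_pressure."""
        geom = lv.geometry
        ap = dataclasses.replace(lv.active, l0=2.0, Tmax=150.0)
        pp_a = _fast.pack_passive(lv.passive)
        ap_a = _fast.pack_active(ap)
        for _ in range(20):
            ri = geom.Ri * rng.uniform(0.85, 1.3)
            t = rng.uniform(0.0, 0.8)
            ref = rl.chamber_pressure(ri, t, lv.passive, ap, geom)
            fast = _fast.chamber_pressure_fast(ri, t, pp_a, ap_a, geom.Ri, geom.Ro, geom.n_layers)
            assert fast == pytest.approx(ref, rel=1e-8, abs=1e-10)


class TestSimulateCycle:
    def test_trace_grid_contract(self, contracting, cfg):
        lv, rv = contracting
        trace, _ = rl.simulate_cycle(lv, rv, cfg.pv.circulation)
        assert trace.n == 401
        assert trace.t[0] == 0.0
        assert trace.t[-1] == pytest.approx(cfg.pv.circulation.T_cycle)

    def test_limit_cycle_reached(self, contracting, cfg):
        lv, rv = contracting
        t_lv, t_rv = rl.simulate_cycle(lv, rv, cfg.pv.circulation)
        for tr in (t_lv, t_rv):
            assert tr.volume_drift < 0.01 * tr.stroke_volume

    def test_loop_work_positive(self, contracting, cfg):
        lv, rv = contracting
        trace, _ = rl.simulate_cycle(lv, rv, cfg.pv.circulation)
        stroke_work = -np.trapezoid(trace.P, trace.V)  # enclosed PV-loop area
        assert stroke_work > 0

    def test_passive_chambers_do_not_eject(self, cfg):
        quiet = dataclasses.replace(cfg.pv.active_base, Tmax=0.0)
        lv = dataclasses.replace(cfg.lv_spec(), active=quiet)
        rv = dataclasses.replace(cfg.rv_spec(), active=quiet)
        trace, _ = rl.simulate_cycle(lv, rv, cfg.pv.circulation)
        assert trace.stroke_volume < 0.5
        dVdt = np.gradient(trace.V, trace.t)
        assert abs(dVdt[-1]) < 1.0  # approaching the static filled value

    def test_rv_preload_coupling_informative(self, contracting, cfg):
        lv, rv = contracting
        base, _ = rl.simulate_cycle(lv, rv, cfg.pv.circulation)
        rv_weak = dataclasses.replace(
            rv, active=dataclasses.replace(rv.active, l0=rv.active.l0 * 1.2)
        )
        pert, _ = rl.simulate_cycle(lv, rv_weak, cfg.pv.circulation)
        assert np.abs(base.P - pert.P).max() > 0.5

    def test_deterministic(self, contracting, cfg):
        lv, rv = contracting
        a, _ = rl.simulate_cycle(lv, rv, cfg.pv.circulation)
        b, _ = rl.simulate_cycle(lv, rv, cfg.pv.circulation)
        assert np.array_equal(a.P, b.P) and np.array_equal(a.V, b.V)


class TestEDMesh:
    def test_element_count(self, mesh):
        assert mesh.n_elements == 576

    def test_centroids_on_spheroid_surface(self, mesh):
        g = mesh.geometry
        residual = (mesh.r / g.b0) ** 2 + (mesh.z / g.c0) ** 2 - 1.0
        assert np.abs(residual).max() < 1e-9

    def test_24_equispaced_circumferential_stations(self, mesh):
        thetas = np.unique(np.round(mesh.theta, 12))
        assert len(thetas) == 24
        assert np.allclose(np.diff(thetas), 2 * math.pi / 24)

    def test_grid_positions_unique(self, mesh):
        pairs = set(zip(np.round(mesh.theta, 9), np.round(mesh.z, 9)))
        assert len(pairs) == mesh.n_elements

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(rl.ConfigError):
            rl.SpheroidGeometry(b0=-1.0)
        with pytest.raises(rl.ConfigError):
            rl.SpheroidGeometry(apex_cut=3.0)


class TestEDInflation:
    def test_unloaded_gives_zero_inflation(self, mesh):
        assert rl.ed_inflation_solve(PassiveParams(), 0.0, mesh) == 0.0

    def test_inflation_monotone_in_pressure(self, mesh):
        pp = PassiveParams()
        kappas = [rl.ed_inflation_solve(pp, P, mesh) for P in (4.0, 8.0, 16.38, 25.0)]
        assert np.all(np.diff(kappas) > 0)

    def test_stiffening_reduces_inflation(self, mesh):
        pp = PassiveParams()
        stiff = PassiveParams(a=pp.a * 10, a_f=pp.a_f * 10, a_s=pp.a_s * 10, a_fs=pp.a_fs * 10)
        assert rl.ed_inflation_solve(stiff, 16.38, mesh) < rl.ed_inflation_solve(pp, 16.38, mesh)

    def test_solved_pressure_matches_target(self, mesh):
        pp = PassiveParams()
        kappa = rl.ed_inflation_solve(pp, 16.38, mesh)
        assert abs(rl._inflation_pressure(mesh, pp, kappa) - 16.38) < 0.01


class TestEDStress:
    def test_unloaded_field_is_stress_free(self, mesh):
        records = rl.ed_stress_field(PassiveParams(), 0.0, mesh)
        assert len(records) == 576
        assert max(abs(r.S11) + abs(r.S22) + abs(r.S12) for r in records) < 1e-12

    def test_equibiaxial_stretch_has_no_shear(self):
        """Equal in-plane stretches make the tangent stress isotropic."""
        _, _, s12 = rl.tangent_stress_components(
            1.15, 1.15, math.radians(45.0), PassiveParams(), endo_pressure_kpa=2.18
        )
        assert abs(s12) < 1e-12

    def test_regional_variation_present(self, mesh):
        records = rl.ed_stress_field(PassiveParams(), 16.38, mesh)
        s11 = np.array([r.S11 for r in records])
        assert s11.std() > 0.05

    def test_deformed_coordinates_outside_reference(self, mesh):
        records = rl.ed_stress_field(PassiveParams(), 16.38, mesh)
        r_def = np.array([rec.r for rec in records])
        assert np.all(r_def > mesh.r)  # inflation moves centroids outward


PV_RANGES = ParameterRanges.from_items([
    ("l0_LV", 1.5, 2.8, "um"), ("l0_RV", 1.5, 2.8, "um"),
    ("t0_LV", 0.075, 0.25, "s"), ("t0_RV", 0.075, 0.25, "s"),
    ("Tmax_LV", 65.0, 190.0, "kPa"), ("Tmax_RV", 65.0, 190.0, "kPa"),
])


@pytest.fixture(scope="module")
def pv_small(cfg):
    plan = latin_hypercube(5, PV_RANGES, seed=42)
    return rl.generate_pv_dataset(
        plan, cfg.lv_spec(), cfg.rv_spec(), cfg.pv.circulation,
        n_train=3, n_test=2, seed=9,
    )


class TestPVDataset:
    RANGES = PV_RANGES

    def test_row_counts_and_schema(self, pv_small):
        train, test = pv_small
        assert len(train) == 3 * 401 and len(test) == 2 * 401
        assert list(train.columns) == [
            "cycle_id", "l0_LV", "l0_RV", "t0_LV", "t0_RV",
            "Tmax_LV", "Tmax_RV", "t", "P_LV", "V_LV",
        ]

    def test_split_disjoint_by_cycle(self, pv_small):
        train, test = pv_small
        assert not set(train.cycle_id) & set(test.cycle_id)

    def test_features_within_ranges(self, pv_small):
        train, test = pv_small
        full = pd.concat([train, test])
        for name, lo, hi in zip(self.RANGES.names, self.RANGES.lows, self.RANGES.highs):
            assert full[name].between(lo, hi).all()

    def test_same_seed_reproduces_tables_exactly(self, cfg, pv_small):
        plan = latin_hypercube(5, self.RANGES, seed=42)
        train2, _ = rl.generate_pv_dataset(
            plan, cfg.lv_spec(), cfg.rv_spec(), cfg.pv.circulation,
            n_train=3, n_test=2, seed=9,
        )
        assert pv_small[0].to_csv(index=False) == train2.to_csv(index=False)


STRESS_RANGES = ParameterRanges.from_items([
    ("a", 0.229e-3, 9.881e-3, "MPa"), ("a_s", 9.1e-5, 6.986e-3, "MPa"),
    ("a_f", 0.5e-3, 49.901e-3, "MPa"), ("a_fs", 7.568e-5, 3.952e-3, "MPa"),
])


@pytest.fixture(scope="module")
def stress_small(cfg):
    plan = latin_hypercube(6, STRESS_RANGES, seed=4)
    return rl.generate_stress_dataset(
        plan, cfg.stress.geometry, n_train=4, n_test=2, seed=5,
        PED=16.38, base_passive=cfg.stress.base_passive(),
    )


class TestStressDataset:
    RANGES = STRESS_RANGES

    def test_row_counts_and_schema(self, stress_small):
        train, test = stress_small
        assert len(train) == 4 * 576 and len(test) == 2 * 576
        assert list(train.columns) == [
            "model_id", "element_id", "a", "a_s", "a_f", "a_fs",
            "r", "theta", "z", "S11", "S22", "S12",
        ]

    def test_features_in_printed_mpa_ranges(self, stress_small):
        full = pd.concat(stress_small)
        for name, lo, hi in zip(self.RANGES.names, self.RANGES.lows, self.RANGES.highs):
            assert full[name].between(lo, hi).all()

    def test_same_seed_reproduces_tables_exactly(self, cfg, stress_small):
        plan = latin_hypercube(6, self.RANGES, seed=4)
        train2, _ = rl.generate_stress_dataset(
            plan, cfg.stress.geometry, n_train=4, n_test=2, seed=5,
            PED=16.38, base_passive=cfg.stress.base_passive(),
        )
        assert stress_small[0].to_csv(index=False) == train2.to_csv(index=False)
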