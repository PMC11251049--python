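"""Lame ring solution, modulus fixed point and slice-stack inflation."""

import numpy as np
import pytest
from scipy.optimize import brentq

from vesselmech.inflation import (
    MMHG_TO_MPA,
    VesselGeometry,
    lame_ring,
    marker_distensibility,
    nonlinear_ring,
    simulate_compliance_experiment,
    vessel_pv_curve,
)
from vesselmech.material import MaterialSpec, ModulusTable, evaluate_modulus
from vesselmech.synthetic import gen_vessel_geometry

# frozen from an independent symbolic (sympy) evaluation of the Lame
# closed form at a=3 mm, t=1 mm, E=0.31 MPa, nu=0.4, p=100 mmHg
U_A_CLOSED = 0.446046328402258
U_A_PLANE_STRAIN = 0.459317128255548


class TestLameRing:
    def test_unloaded_state_is_reference(self):
        st = lame_ring(3.0, 1.0, 0.31, 0.4, 0.0)
        assert st.inner_radius_deformed == pytest.approx(3.0, abs=1e-15)
        assert st.outer_radius_deformed == pytest.approx(4.0, abs=1e-15)
        assert st.hoop_strain == 0.0 and st.radial_strain == 0.0

    @pytest.mark.parametrize(
        "end, expected", [("closed", U_A_CLOSED), ("plane_strain", U_A_PLANE_STRAIN)]
    )
    def test_symbolic_oracle_displacement(self, end, expected):
        st = lame_ring(3.0, 1.0, 0.31, 0.4, 100.0, end)
        assert st.inner_radius_deformed - 3.0 == pytest.approx(expected, rel=1e-12)

    def test_linearity_in_inverse_modulus(self):
        u1 = lame_ring(3.0, 1.0, 0.31, 0.4, 100.0).inner_radius_deformed - 3.0
        u2 = lame_ring(3.0, 1.0, 0.62, 0.4, 100.0).inner_radius_deformed - 3.0
        assert u1 == pytest.approx(2.0 * u2, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lame_ring(3.0, 0.0, 0.31)
        with pytest.raises(ValueError):
            lame_ring(3.0, 1.0, -0.31)

    def test_thin_shell_limit_first_order(self):
        # plane-strain inner-radius distensibility per unit pressure must
        # approach a(1-nu^2)/(E t) with first-order rate in t/a
        a, E, nu, p = 5.0, 1.0, 0.4, 10.0
        errs = []
        ratios = [0.1, 0.05, 0.025, 0.0125]
        for ta in ratios:
            t = ta * a
            st = lame_ring(a, t, E, nu, p, "plane_strain")
            dist = (st.inner_radius_deformed - a) / (a * p * MMHG_TO_MPA)
            errs.append(abs(dist / (a * (1 - nu**2) / (E * t)) - 1.0))
        rates = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(np.abs(rates - 1.0) < 0.1)


class TestNonlinearRing:
    def test_constant_material_matches_lame_immediately(self):
        mat = MaterialSpec.constant(0.31)
        st = nonlinear_ring(3.0, 1.0, mat, 100.0)
        ref = lame_ring(3.0, 1.0, 0.31, 0.4, 100.0)
        assert st.inner_radius_deformed == ref.inner_radius_deformed
        assert st.iterations <= 2

    def test_constant_table_equals_constant_mode(self):
        table = MaterialSpec.from_table(ModulusTable([0.0, 0.5], [0.31, 0.31]))
        st = nonlinear_ring(3.0, 1.0, table, 100.0)
        ref = lame_ring(3.0, 1.0, 0.31, 0.4, 100.0)
        u, u_ref = st.inner_radius_deformed - 3.0, ref.inner_radius_deformed - 3.0
        assert abs(u / u_ref - 1.0) < 1e-10

    def test_softening_table_against_scalar_root_oracle(self, softening_mat):
        # the fixed point solves E = table(k_m p / E); an independent 1-D
        # root bracketing of g(E) = E - table(k_m p / E) must agree
        p = 120.0
        st = nonlinear_ring(3.0, 1.0, softening_mat, p)
        ref = lame_ring(3.0, 1.0, 1.0, 0.4, p)  # E=1 gives the strain coefficient
        k_m = ref.epsilon_m  # eps_m per unit (p/E) times p already applied
        table = softening_mat.table

        def g(E):
            return E - float(table(k_m / E))

        E_root = brentq(g, 0.01, 1.0, xtol=1e-12)
        assert st.E_used == pytest.approx(E_root, rel=1e-7)
        # softening increases the hoop strain vs the stiff constant run
        const = lame_ring(3.0, 1.0, 0.36, 0.4, p)
        assert st.hoop_strain > const.hoop_strain

    def test_epsilon_m_consistent_with_metric(self, softening_mat):
        st = nonlinear_ring(3.0, 1.0, softening_mat, 120.0)
        assert st.E_used == pytest.approx(
            float(evaluate_modulus(softening_mat, st.epsilon_m)), rel=1e-7
        )


class TestVesselPvCurve:
    def test_rigid_limit_volume_constant(self, tube):
        mat = MaterialSpec.constant(1e6)
        res = vessel_pv_curve(tube, mat, [0.0, 100.0, 200.0])
        assert np.all(np.abs(res.volumes / tube.lumen_volume() - 1.0) < 1e-4)

    def test_uniform_tube_matches_single_ring_closed_form(self, tube, const_mat):
        p = 100.0
        res = vessel_pv_curve(tube, const_mat, [p])
        ring = lame_ring(3.0, 1.0, 0.31, 0.4, p)
        expected = np.pi * ring.inner_radius_deformed**2 * 50.0
        assert res.volumes[0] == pytest.approx(expected, rel=1e-12)
        np.testing.assert_allclose(
            res.station_diameters[0], 2.0 * ring.inner_radius_deformed, rtol=1e-12
        )

    def test_volume_and_diameters_nondecreasing(self, stenotic, softening_mat):
        pressures = np.linspace(0.0, 140.0, 15)
        res = vessel_pv_curve(stenotic, softening_mat, pressures)
        assert np.all(np.diff(res.volumes) >= 0.0)
        assert np.all(np.diff(res.station_diameters, axis=0) >= 0.0)

    def test_stenotic_station_stiffest(self, stenotic, const_mat):
        res = vessel_pv_curve(stenotic, const_mat, [0.0, 60.0, 130.0])
        gain = res.station_diameters[-1] - res.station_diameters[0]
        assert np.argmin(gain) == stenotic.site_markers["ICAs"]

    def test_incremental_agrees_with_direct_at_small_strain(self, stenotic):
        # stiff enough that the worst-station mid-wall hoop strain stays
        # below ~3.5%, where geometric nonlinearity is second order
        mat = MaterialSpec.constant(1.3)
        d = vessel_pv_curve(stenotic, mat, [130.0])
        i = vessel_pv_curve(stenotic, mat, [130.0], stepping="incremental")
        assert abs(i.volumes[0] / d.volumes[0] - 1.0) < 0.005

    def test_constant_table_equivalence_full_vessel(self, stenotic, const_mat):
        table_mat = MaterialSpec.from_table(ModulusTable([0.0, 0.5], [0.31, 0.31]))
        pressures = [0.0, 40.0, 80.0, 130.0]
        r1 = vessel_pv_curve(stenotic, table_mat, pressures)
        r2 = vessel_pv_curve(stenotic, const_mat, pressures)
        np.testing.assert_allclose(r1.volumes, r2.volumes, rtol=1e-10)

    def test_bad_pressures_rejected(self, tube, const_mat):
        with pytest.raises(ValueError):
            vessel_pv_curve(tube, const_mat, [100.0, 50.0])
        with pytest.raises(ValueError):
            vessel_pv_curve(tube, const_mat, [-1.0, 50.0])


class TestComplianceSimulation:
    def test_rigid_material_zero_compliance(self, tube):
        rep = simulate_compliance_experiment(tube, MaterialSpec.constant(1e6))
        assert rep.C_V == pytest.approx(0.0, abs=1e-6)

    def test_cv_independent_of_tube_length(self, const_mat):
        reps = []
        for L in (30.0, 60.0, 120.0):
            geom = gen_vessel_geometry(length=L, base_radius=3.0, base_thickness=1.0)
            reps.append(simulate_compliance_experiment(geom, const_mat).C_V)
        assert reps[0] == pytest.approx(reps[1], rel=1e-10)
        assert reps[1] == pytest.approx(reps[2], rel=1e-10)

    def test_tube_cv_from_lame_closed_form(self, tube, const_mat):
        # direct-mode C_V must equal the single-ring closed form at 74/130
        r_d = lame_ring(3.0, 1.0, 0.31, 0.4, 74.0).inner_radius_deformed
        r_s = lame_ring(3.0, 1.0, 0.31, 0.4, 130.0).inner_radius_deformed
        V_d, V_s = np.pi * r_d**2 * 50.0, np.pi * r_s**2 * 50.0
        expected = (V_s - V_d) / (V_d * 56.0) * 100.0
        rep = simulate_compliance_experiment(tube, const_mat)
        assert rep.C_V == pytest.approx(expected, rel=1e-12)
        assert rep.provenance == "model"

    def test_cv_monotone_in_stiffness_and_thickness(self):
        cvs = [
            simulate_compliance_experiment(
                gen_vessel_geometry(length=40.0, base_radius=3.0, base_thickness=1.0),
                MaterialSpec.constant(E),
            ).C_V
            for E in (0.31, 0.62, 1.24, 2.48)
        ]
        assert np.all(np.diff(cvs) < 0.0)
        cvt = [
            simulate_compliance_experiment(
                gen_vessel_geometry(length=40.0, base_radius=3.0, base_thickness=t),
                MaterialSpec.constant(0.62),
            ).C_V
            for t in (0.5, 1.0, 1.5, 2.0)
        ]
        assert np.all(np.diff(cvt) < 0.0)


class TestMarkerDistensibility:
    def test_rigid_zero_everywhere(self, stenotic):
        cd = marker_distensibility(stenotic, MaterialSpec.constant(1e6))
        assert all(abs(v) < 1e-6 for v in cd.values())

    def test_uniform_tube_all_sites_equal(self, tube, const_mat):
        cd = marker_distensibility(tube, const_mat)
        vals = list(cd.values())
        assert max(vals) == pytest.approx(min(vals), rel=1e-12)

    def test_stenotic_site_is_minimum(self, stenotic, const_mat):
        cd = marker_distensibility(stenotic, const_mat)
        assert cd["ICAs"] == min(cd.values())
        assert cd["ICAs"] < cd["CCA"]

    def test_missing_markers_error(self, const_mat):
        geom = VesselGeometry(
            z=[0.0, 1.0, 2.0], inner_radius=[3.0] * 3, thickness=[1.0] * 3
        )
        with pytest.raises(ValueError, match="marker"):
            marker_distensibility(geom, const_mat)
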