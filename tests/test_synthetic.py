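import numpy as np
import pytest

from oofrecon import (BeamModelParams, DetectorGeometry, DoseGrid,
                      ExposureState, aperture_at, diode_positions,
                      exposure_state, generate_plan, ratio_of_ratios,
                      segment_subbeams, sensitivity_ratio_analysis,
                      toy_subbeam_dose, virtual_diode_readings)
from oofrecon.synthetic import (CALIBRATION_REP_RATE, CALIBRATION_SDD_MM,
                                ResponseModel, ToyDoseParams, toy_dose_at_points)


class TestGeneratePlan:
    def test_static_has_two_control_points(self):
        plan = generate_plan("static", (100.0, 100.0), total_mu=100.0)
        assert len(plan.beams[0].control_points) == 2

    def test_full_arc_control_point_count(self):
        plan = generate_plan("arc", n_control_points=181, total_mu=360.0)
        cps = plan.beams[0].control_points
        assert len(cps) == 181
        assert cps[-1].gantry_angle - cps[0].gantry_angle == pytest.approx(360.0)

    def test_oof_test_aperture_puts_isocenter_under_mlc(self):
        plan = generate_plan("oof_test", aperture_width=5.0, point_offset=10.0)
        beam = plan.beams[0]
        ap = aperture_at(beam, 50.0)
        assert exposure_state(ap, (0.0, 0.0)) == ExposureState.UNDER_MLC
        # the measurement point is 10 mm outside the nearest field edge
        assert ap.leaf_positions[1].max() == pytest.approx(-10.0)

    def test_deterministic_given_seed(self):
        a = generate_plan("arc", n_control_points=10, leaf_jitter=3.0, seed=5)
        b = generate_plan("arc", n_control_points=10, leaf_jitter=3.0, seed=5)
        for ca, cb in zip(a.beams[0].control_points, b.beams[0].control_points):
            assert np.array_equal(ca.leaf_positions, cb.leaf_positions)


class TestToyDose:
    def _setup(self):
        plan = generate_plan("static", (100.0, 100.0), total_mu=100.0)
        beam = plan.beams[0]
        sb = segment_subbeams(beam)[0]
        return beam, sb, DetectorGeometry(), ToyDoseParams(), BeamModelParams()

    def test_dose_positive_and_linear_in_mu(self):
        beam, sb, phantom, params, model = self._setup()
        iso = np.array([[0.0, 0.0, 0.0]])
        d1, _ = toy_dose_at_points(iso, sb, beam, phantom, params, model)
        assert d1[0] > 0
        plan2 = generate_plan("static", (100.0, 100.0), total_mu=200.0)
        sb2 = segment_subbeams(plan2.beams[0])[0]
        d2, _ = toy_dose_at_points(iso, sb2, plan2.beams[0], phantom, params, model)
        assert d2[0] == pytest.approx(2 * d1[0])

    def test_collimated_ray_gets_scatter_floor_plus_transmission(self):
        beam, sb, phantom, params, model = self._setup()
        inside = np.array([[0.0, 0.0, 0.0]])
        outside = np.array([[70.0, 0.0, 0.0]])  # 20 mm outside the 100 mm field
        d_in, c_in = toy_dose_at_points(inside, sb, beam, phantom, params, model)
        d_out, c_out = toy_dose_at_points(outside, sb, beam, phantom, params, model)
        assert not c_in[0] and c_out[0]
        # ratio ~ scatter + T_jaw, up to the slightly shorter water path of
        # the off-axis ray through the cylinder (~10%)
        assert d_out[0] / d_in[0] == pytest.approx(
            params.scatter_floor + model.jaw_transmission, rel=0.15)

    def test_entrance_exit_shell_ratio_near_four(self):
        """Exit diode-shell dose is about one quarter of the entrance one."""
        beam, sb, phantom, params, model = self._setup()
        entrance = np.array([[0.0, 0.0, phantom.array_radius]])
        exit_ = np.array([[0.0, 0.0, -phantom.array_radius]])
        d_en, _ = toy_dose_at_points(entrance, sb, beam, phantom, params, model)
        d_ex, _ = toy_dose_at_points(exit_, sb, beam, phantom, params, model)
        assert d_en[0] / d_ex[0] == pytest.approx(4.0, abs=0.4)

    def test_grid_version_matches_point_version(self):
        beam, sb, phantom, params, model = self._setup()
        lattice = DoseGrid(np.array([-50.0, -20.0, -50.0]),
                           np.array([25.0, 20.0, 25.0]), np.zeros((5, 3, 5)))
        g = toy_subbeam_dose(sb, beam, phantom, lattice, params, model)
        pts = lattice.voxel_centers()
        d, _ = toy_dose_at_points(pts, sb, beam, phantom, params, model)
        assert np.array_equal(g.values.ravel(), d)


class TestDiodePositions:
    def test_on_cylinder_surface_and_deterministic(self):
        geom = DetectorGeometry()
        pts = diode_positions(geom, 200)
        r = np.hypot(pts[:, 0], pts[:, 2])
        assert np.allclose(r, geom.array_radius)
        assert np.array_equal(pts, diode_positions(geom, 200))


class TestVirtualReadings:
    def test_identity_model_returns_true_dose(self):
        dose = np.array([[1.0, 2.0], [0.5, 0.25]])
        col = np.zeros_like(dose, dtype=bool)
        r = virtual_diode_readings(dose, [50.0, 50.0], 400.0, np.array([896.0, 896.0]),
                                   col, ResponseModel.identity())
        assert np.array_equal(r, dose.sum(axis=0))

    def test_oof_overresponse_on_fully_blocked_diode(self):
        dose = np.array([[1.0, 1.0]])
        col = np.array([[False, True]])
        model = ResponseModel(oof_overresponse=1.17)
        r = virtual_diode_readings(dose, [50.0], 400.0, np.array([896.0, 896.0]),
                                   col, model)
        assert r[0] == pytest.approx(1.0)
        assert r[1] == pytest.approx(1.17)

    def test_rep_rate_anchor_at_5_mu_per_min(self):
        model = ResponseModel.from_packaged()
        dose = np.array([[1.0]])
        col = np.array([[False]])
        r = virtual_diode_readings(dose, [100.0], 5.0, np.array([896.0]), col, model)
        assert r[0] == pytest.approx(0.978)

    def test_noise_reproducible_for_a_seed(self):
        dose = np.ones((3, 10))
        col = np.zeros_like(dose, dtype=bool)
        m = ResponseModel(noise_sd=0.01, seed=42)
        a = virtual_diode_readings(dose, [10, 10, 10], 400.0, np.full(10, 896.0), col, m)
        b = virtual_diode_readings(dose, [10, 10, 10], 400.0, np.full(10, 896.0), col, m)
        assert np.array_equal(a, b)


class TestSensitivityRatios:
    def test_identical_series_gives_unity(self):
        c = np.array([5.0, 100.0, 400.0, 600.0])
        r = sensitivity_ratio_analysis(c, np.ones(4), np.ones(4), normalize_at=400.0)
        assert np.allclose(r["ratio"], 1.0)

    def test_missing_normalization_condition_rejected(self):
        with pytest.raises(ValueError, match="normalization"):
            sensitivity_ratio_analysis(np.array([5.0, 100.0]), np.ones(2), np.ones(2),
                                       normalize_at=400.0)

    def test_closed_loop_recovers_rep_rate_curve(self):
        """Readings simulated with the packaged curve, normalized against a
        perfect reference, reproduce the curve anchors."""
        model = ResponseModel.from_packaged()
        rates = np.array([5.0, 100.0, 400.0, 600.0])
        true = np.ones_like(rates)
        device = np.array([
            virtual_diode_readings(np.array([[1.0]]), [50.0], rr, np.array([896.0]),
                                   np.array([[False]]), model)[0]
            for rr in rates
        ])
        table = sensitivity_ratio_analysis(rates, device, true,
                                           normalize_at=CALIBRATION_REP_RATE)
        assert table["ratio"].to_numpy() == pytest.approx([0.978, 0.993, 1.0, 1.001])

    def test_ratio_of_ratios_recovers_hardware_overresponse(self):
        """Two hardware versions measured out-of-field against the same
        chamber reference differ by the out-of-field overresponse factor."""
        conditions = np.array([0.0, 1.0, 2.0])  # 0 = open-field normalization
        true = np.array([1.0, 0.05, 0.04])

        def device(version):
            m = ResponseModel.from_packaged(hardware_version=version)
            readings = []
            for dose, cond in zip(true, conditions):
                col = np.array([[cond != 0.0]])  # only the OOF points are blocked
                readings.append(virtual_diode_readings(
                    np.array([[dose]]), [50.0], 400.0, np.array([896.0]), col, m)[0])
            return np.array(readings)

        t1 = sensitivity_ratio_analysis(conditions, device("v1"), true, normalize_at=0.0)
        t2 = sensitivity_ratio_analysis(conditions, device("v2"), true, normalize_at=0.0)
        rr = ratio_of_ratios(t1, t2)
        oof_rows = rr["condition"] != 0.0
        assert rr.loc[oof_rows, "ratio"].to_numpy() == pytest.approx(1.17)

    def test_dpp_curve_anchors(self):
        model = ResponseModel.from_packaged(energy="6X")
        assert model.dpp(746.0) == pytest.approx(1.012)
        assert model.dpp(CALIBRATION_SDD_MM) == pytest.approx(1.0)
        assert model.dpp(1196.0) == pytest.approx(0.992)

    def test_low_mu_anchor_minus_2_8_percent_at_2mu(self):
        model = ResponseModel.from_packaged(acquisition="default", diode="entrance")
        assert model.low_mu(2.0) == pytest.approx(0.972)
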