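"""Virtual sensors: solid angles, placement, normalization identity,
calibration and treatment monitoring."""

import math

import numpy as np
import pytest
from scipy import integrate

import cavidose as cv
from cavidose.sensors import TracePattern


class TestAcceptanceSolidAngle:
    def test_full_hemisphere(self):
        assert cv.acceptance_solid_angle(1.33, 1.33) == pytest.approx(2 * math.pi)

    def test_na_0625_in_water(self):
        assert cv.acceptance_solid_angle(0.625, 1.33) == pytest.approx(0.737, abs=1e-3)

    def test_vanishing_na(self):
        assert cv.acceptance_solid_angle(1e-9, 1.33) == pytest.approx(0.0, abs=1e-12)

    def test_na_above_medium_rejected(self):
        with pytest.raises(ValueError):
            cv.acceptance_solid_angle(1.5, 1.33)


class TestPlacement:
    def test_single_is_one_cut_end_at_neck(self, sphere48):
        specs = cv.build_sensor_set(sphere48, "single")
        assert len(specs) == 1
        assert specs[0].kind == "cut_end"
        assert specs[0].position[2] < 0  # neck pole is -z
        assert specs[0].axis @ np.array([0, 0, 1.0]) > 0.99  # aimed at the void

    def test_triple_polish_angle(self, sphere48):
        specs = cv.build_sensor_set(sphere48, "triple")
        assert len(specs) == 3
        assert all(s.polish_angle_deg == 25.0 for s in specs)
        inward = np.array([0, 0, 1.0])
        for s in specs:
            assert s.axis @ inward == pytest.approx(math.cos(math.radians(25)), abs=1e-6)

    def test_cage12_column_azimuths(self, sphere48):
        specs = cv.build_sensor_set(sphere48, "cage12")
        assert len(specs) == 12
        az = np.degrees(np.arctan2([s.position[1] for s in specs], [s.position[0] for s in specs]))
        az = np.round(np.mod(az, 360.0)).astype(int)
        assert set(az) == {0, 120, 240}
        assert all(s.angular_response == "cosine_squared" for s in specs)

    def test_unknown_implementation(self, sphere48):
        with pytest.raises(ValueError):
            cv.build_sensor_set(sphere48, "dual")


class TestNormalizationIdentity:
    def test_cos2_hemisphere_integral_closed_form(self):
        """The cos^2 angular response integrates to 2 pi / 3 over the
        hemisphere (the stated normalization of the physical probe)."""
        val, _ = integrate.quad(
            lambda a: math.cos(a) ** 2 * 2 * math.pi * math.sin(a), 0, math.pi / 2
        )
        assert val == pytest.approx(2 * math.pi / 3)

    def test_all_kinds_read_e0_in_uniform_diffuse_field(
        self, sphere48, sphere48_patches, diffuse_crossing_log
    ):
        log, e0 = diffuse_crossing_log
        for impl in ("single", "triple", "cage12"):
            bank = cv.SensorBank(cv.build_sensor_set(sphere48, impl), sphere48_patches)
            readings = cv.readings_from_crossings(log, bank)
            for r in readings:
                assert r.irradiance_estimate == pytest.approx(e0, rel=0.05)

    def test_diffuse_divisors_recover_closed_forms_on_sphere(
        self, sphere48, sphere48_patches
    ):
        """With the acceptance axis along the local normal the numeric
        diffuse-field calibration matches sin^2(theta_c) (NA cone) and
        1/2 (cos^2); neighborhood normal spread keeps it a few % low."""
        b1 = cv.SensorBank(cv.build_sensor_set(sphere48, "single"), sphere48_patches)
        theta_c = math.asin(0.625 / 1.33)
        assert b1.divisor[0] == pytest.approx(math.sin(theta_c) ** 2, rel=0.05)
        b12 = cv.SensorBank(cv.build_sensor_set(sphere48, "cage12"), sphere48_patches)
        assert np.allclose(b12.divisor, 0.5, rtol=0.05)
        bi = cv.SensorBank(
            cv.build_sensor_set(sphere48, "cage12"), sphere48_patches, ideal_cosine=True
        )
        assert np.allclose(bi.divisor, 2.0 / 3.0, rtol=0.05)

    def test_cage12_reads_inverse_square_field(
        self, sphere48, sphere48_patches, absorbing_map, central_source
    ):
        """Central source, clear void, absorbing wall: a cos^2 sensor
        over-reads the purely normal-incidence field by ~2x (it is
        calibrated against a diffuse field), so the raw estimate sits
        near 2 P/(4 pi r^2)."""
        bank = cv.SensorBank(cv.build_sensor_set(sphere48, "cage12"), sphere48_patches)
        dm = cv.run_transport(
            sphere48,
            absorbing_map,
            central_source,
            sphere48_patches,
            cv.TransportConfig(n_packets=100_000, seed=31),
            sensor_bank=bank,
        )
        r = sphere48.base_params[0]
        e_true = 2500.0 / (4 * np.pi * r**2) * 100.0
        est = np.array([x.irradiance_estimate for x in cv.sensor_readings(dm, bank)])
        assert np.allclose(est, 2.0 * e_true, rtol=0.10)

    def test_cut_end_cone_gating(self, sphere48, sphere48_patches):
        """A cut-end fiber sees light arriving inside its NA cone and
        nothing arriving well outside it."""
        bank = cv.SensorBank(cv.build_sensor_set(sphere48, "single"), sphere48_patches)
        pset = bank.patch_sets[0]
        n = 1000
        ids = np.repeat(pset, n // len(pset) + 1)[:n]
        on_axis = np.tile(-bank.specs[0].axis, (n, 1))  # arriving along the axis
        w = np.ones(n)
        r_on = cv.readings_from_crossings((ids, on_axis, w), bank)[0]
        assert r_on.accepted_weight == pytest.approx(n)
        # rotate arrival 40 deg off-axis: beyond the 28-deg cone
        ax = bank.specs[0].axis
        perp = np.cross(ax, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        off = -(math.cos(math.radians(40)) * ax + math.sin(math.radians(40)) * perp)
        r_off = cv.readings_from_crossings((ids, np.tile(off, (n, 1)), w), bank)[0]
        assert r_off.accepted_weight == 0.0


class TestMeanIrradianceRatio:
    def test_perfect_sensors_give_one(self, preset_run):
        true_mean = preset_run.mean_wall_irradiance
        readings = [
            cv.SensorReading(true_mean, 1.0, f"s{i}") for i in range(3)
        ]
        assert cv.mean_irradiance_ratio(preset_run, readings) == pytest.approx(1.0)

    def test_zero_sensor_mean_rejected(self, preset_run):
        readings = [cv.SensorReading(0.0, 0.0, "s0")]
        with pytest.raises(ValueError):
            cv.mean_irradiance_ratio(preset_run, readings)


class TestCalibration:
    def test_water_deployment_factor(self):
        assert cv.apply_calibration(10.0, 1.0, "water") == pytest.approx(15.8)

    def test_air_no_correction(self):
        assert cv.apply_calibration(10.0, 2.0, "air") == pytest.approx(5.0)

    def test_linearity(self):
        assert cv.apply_calibration(8.0, 1.3, "water") == pytest.approx(
            2.0 * cv.apply_calibration(4.0, 1.3, "water")
        )

    def test_nonpositive_responsivity_rejected(self):
        with pytest.raises(ValueError):
            cv.apply_calibration(1.0, 0.0)


class TestMonitoring:
    def test_constant_trace_terminates_at_3000s(self):
        t = np.arange(0.0, 4001.0, 1.0)
        trace = cv.IrradianceTrace(time=t, irradiance=np.full((t.size, 4), 30.0))
        out = cv.integrate_exposure(trace, target_J_cm2=90.0)
        assert out["termination_time_s"] == pytest.approx(3000.0, abs=1e-6)
        assert out["reached_target"]
        assert np.allclose(out["per_sensor_exposure_J_cm2"], 90.0, rtol=1e-6)

    def test_interruption_shifts_termination_additively(self):
        t = np.arange(0.0, 4601.0, 1.0)
        irr = np.full((t.size, 4), 30.0)
        trace = cv.IrradianceTrace(
            time=t, irradiance=irr, interruption_intervals=[(1000.0, 1600.0)]
        )
        out = cv.integrate_exposure(trace, target_J_cm2=90.0)
        assert out["termination_time_s"] == pytest.approx(3600.0, abs=1e-6)

    def test_dead_sensor_excluded_from_average(self):
        t = np.arange(0.0, 4001.0, 1.0)
        irr = np.full((t.size, 4), 30.0)
        irr[:, 2] = 0.0
        trace = cv.IrradianceTrace(time=t, irradiance=irr)
        out = cv.integrate_exposure(trace, target_J_cm2=90.0)
        assert not out["responding"][2]
        assert out["termination_time_s"] == pytest.approx(3000.0, abs=1e-6)

    def test_no_responding_sensors_raises(self):
        t = np.arange(0.0, 100.0, 1.0)
        trace = cv.IrradianceTrace(time=t, irradiance=np.zeros((t.size, 3)))
        with pytest.raises(ValueError):
            cv.integrate_exposure(trace, target_J_cm2=90.0, responding_threshold=1.0)

    def test_time_grid_refinement_invariance(self):
        rng = np.random.default_rng(4)
        tc = np.arange(0.0, 5001.0, 10.0)
        base = 25.0 + 5.0 * np.sin(tc / 500.0)
        coarse = cv.IrradianceTrace(time=tc, irradiance=base[:, None])
        tf = np.arange(0.0, 5001.0, 1.0)
        fine = cv.IrradianceTrace(
            time=tf, irradiance=np.interp(tf, tc, base)[:, None]
        )
        a = cv.integrate_exposure(coarse, 60.0)["termination_time_s"]
        b = cv.integrate_exposure(fine, 60.0)["termination_time_s"]
        assert a == pytest.approx(b, abs=2.0)

    def test_baseline_offset_subtracted(self):
        t = np.arange(0.0, 4001.0, 1.0)
        trace = cv.IrradianceTrace(
            time=t, irradiance=np.full((t.size, 2), 31.0), baseline_offset=1.0
        )
        out = cv.integrate_exposure(trace, target_J_cm2=90.0)
        assert out["termination_time_s"] == pytest.approx(3000.0, abs=1e-6)


class TestSynthTrace:
    def test_deterministic_given_seed(self):
        p = TracePattern(noise_frac=0.05)
        a = cv.synth_trace(p, seed=9)
        b = cv.synth_trace(p, seed=9)
        assert np.array_equal(a.irradiance, b.irradiance)

    def test_clean_pattern_is_constant(self):
        p = TracePattern(noise_frac=0.0, sensor_spread=0.0, baseline_offset=0.0)
        tr = cv.synth_trace(p, seed=0)
        assert np.allclose(tr.irradiance, 30.0)

    def test_negative_drift_delays_termination(self):
        const = cv.synth_trace(
            TracePattern(sensor_spread=0.0, baseline_offset=0.0, duration_s=6000), 1
        )
        drift = cv.synth_trace(
            TracePattern(
                sensor_spread=0.0, baseline_offset=0.0, drift_frac=-0.2, duration_s=6000
            ),
            1,
        )
        t_const = cv.integrate_exposure(const, 90.0)["termination_time_s"]
        t_drift = cv.integrate_exposure(drift, 90.0)["termination_time_s"]
        assert t_drift > t_const

    def test_interruptions_recorded(self):
        tr = cv.synth_trace(TracePattern(interruptions=[(500.0, 120.0)]), 2)
        assert tr.interruption_intervals == [(500.0, 620.0)]
        sel = (tr.time >= 500.0) & (tr.time < 620.0)
        assert np.all(tr.net_irradiance()[sel] == 0.0)
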