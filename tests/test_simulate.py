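"""Forward-model tests: waveform primitives, gravity geometry, cohort
structure, and pressure-strain loop generation."""

from dataclasses import replace

import numpy as np
import pytest

from cardimu.simulate import (
    DEFAULT_PROTOCOL,
    REFERENCE_PARAMS,
    Geometry,
    InterventionParams,
    NoiseConfig,
    kinematic_waveform,
    simulate_cohort,
    simulate_pressure_strain,
    simulate_subject,
)
from cardimu.work import loop_work, strain_from_lengths


class TestKinematicWaveform:
    def test_zero_amplitude_is_zero(self):
        t = np.linspace(0, 0.5, 100)
        assert np.all(kinematic_waveform(0.0, 0.25, 0.5, t) == 0.0)

    def test_peak_at_es_delay(self):
        assert kinematic_waveform(9.6, 0.27, 0.55, np.array([0.27]))[0] == pytest.approx(9.6)

    def test_cyclic_returns_to_zero(self):
        val = kinematic_waveform(6.0, 0.27, 0.55, np.array([0.0, 0.55, 1.10]))
        assert np.all(np.abs(val) < 1e-12)

    def test_c1_continuity_at_peak(self):
        # derivative approaches zero from both sides of the peak
        t = np.array([0.27 - 1e-7, 0.27 + 1e-7])
        v = kinematic_waveform(1.0, 0.27, 0.55, t)
        assert abs(v[1] - v[0]) < 1e-9

    def test_invalid_es_delay_raises(self):
        with pytest.raises(ValueError):
            kinematic_waveform(1.0, 0.6, 0.5, np.array([0.1]))
        with pytest.raises(ValueError):
            kinematic_waveform(1.0, 0.0, 0.5, np.array([0.1]))


class TestSimulateSubject:
    def test_static_sensor_reads_pure_gravity(self):
        params = InterventionParams("baseline", 108.0, 0.0, 0.0)
        rec = simulate_subject(params, Geometry(90.0), NoiseConfig.NOISELESS,
                               n_cycles=3, seed=0)
        norms = np.linalg.norm(rec.acc, axis=0)
        assert np.allclose(norms, 9.81, atol=1e-12)
        assert np.ptp(rec.acc, axis=1).max() < 1e-12  # constant vector
        assert np.all(rec.gyro == 0.0)

    def test_true_rotation_peak_matches_parameter(self, baseline_noiseless):
        gt = baseline_noiseless.ground_truth
        # sampled on the 700 S/s grid, so the peak lies within one sample
        # of the analytic maximum
        assert gt.theta_deg.max() == pytest.approx(9.6, abs=2e-3)
        assert gt.rot_esm_deg == 9.6

    def test_horizontal_rotation_plane_has_constant_gravity(self):
        # inclination 0: gravity lies along the rotation axis, so the
        # body-frame gravity components do not vary with rotation
        params = replace(REFERENCE_PARAMS["baseline"], disp_esm_mm=0.0,
                         disp_long_mm=0.0, disp_rad_mm=0.0)
        rec = simulate_subject(params, Geometry(0.0), NoiseConfig.NOISELESS,
                               n_cycles=3, seed=0)
        assert np.ptp(rec.acc, axis=1).max() < 1e-12

    def test_gravity_closure_over_whole_cycles(self, rotation_only_noiseless):
        """With rotation only, the cycle-mean acceleration equals the
        cycle-mean body-frame gravity (no motion contribution)."""
        rec = rotation_only_noiseless
        n0, n1 = rec.r_peaks[0], rec.r_peaks[1]
        acc_mean = rec.acc[:, n0:n1].mean(axis=1)
        theta = np.deg2rad(rec.ground_truth.theta_deg[n0:n1])
        g0 = Geometry(90.0).gravity_start_frame()
        c, s = np.cos(theta), np.sin(theta)
        g_body = np.vstack([np.full_like(theta, g0[0]),
                            c * g0[1] + s * g0[2],
                            -s * g0[1] + c * g0[2]])
        assert np.linalg.norm(acc_mean - g_body.mean(axis=1)) < 1e-6

    @pytest.mark.parametrize("inclination", [0.0, 30.0, 60.0, 90.0])
    def test_artifact_amplitude_scales_with_sin_inclination(self, inclination):
        params = replace(REFERENCE_PARAMS["baseline"], disp_esm_mm=0.0,
                         disp_long_mm=0.0, disp_rad_mm=0.0)
        rec = simulate_subject(params, Geometry(inclination),
                               NoiseConfig.NOISELESS, n_cycles=3, seed=0)
        # peak-to-peak of the circumferential gravity projection
        amp = np.ptp(rec.acc[1])
        ref_rec = simulate_subject(params, Geometry(90.0),
                                   NoiseConfig.NOISELESS, n_cycles=3, seed=0)
        expected = np.ptp(ref_rec.acc[1]) * np.sin(np.deg2rad(inclination))
        assert amp == pytest.approx(expected, rel=1e-2, abs=1e-12)

    def test_n_cycles_minimum(self):
        with pytest.raises(ValueError):
            simulate_subject(REFERENCE_PARAMS["baseline"], n_cycles=2)

    def test_ecg_spikes_at_cycle_starts(self, baseline_noiseless):
        rec = baseline_noiseless
        # unit spike apex 5 samples after each cycle start (triangular rise)
        for k in rec.ground_truth.cycle_starts:
            assert rec.ecg[k + 5] == pytest.approx(1.0)


class TestCohort:
    def test_determinism_under_fixed_seed(self):
        a = simulate_cohort(n_subjects=3, protocol={"baseline": 3, "ischemia": 3},
                            seed=7, n_cycles=3)
        b = simulate_cohort(n_subjects=3, protocol={"baseline": 3, "ischemia": 3},
                            seed=7, n_cycles=3)
        for ra, rb in zip(a.recordings, b.recordings):
            assert ra.subject_id == rb.subject_id
            np.testing.assert_array_equal(ra.acc, rb.acc)
            np.testing.assert_array_equal(ra.gyro, rb.gyro)
            np.testing.assert_array_equal(ra.lvp, rb.lvp)

    def test_default_protocol_counts(self):
        c = simulate_cohort(n_subjects=11, seed=0, n_cycles=3)
        by_label = {}
        for r in c.recordings:
            by_label.setdefault(r.intervention, set()).add(r.subject_id)
        assert len(by_label["baseline"]) == DEFAULT_PROTOCOL["baseline"] == 11
        assert len(by_label["ischemia"]) == 11
        assert len(by_label["dobutamine"]) == 4
        assert len(by_label["dob_isc"]) == 4
        # every subject has a baseline
        assert by_label["baseline"] == set(c.subjects())

    def test_zero_random_effect_makes_subjects_identical(self):
        c = simulate_cohort(n_subjects=2, protocol={"baseline": 2}, seed=1,
                            n_cycles=3, re_sd_scale=0.0,
                            noise=NoiseConfig.NOISELESS)
        r0, r1 = c.recordings
        np.testing.assert_allclose(r0.acc, r1.acc, atol=1e-12)

    def test_invalid_subject_count(self):
        with pytest.raises(ValueError):
            simulate_cohort(n_subjects=0)


class TestPressureStrain:
    def test_constant_pressure_zero_work(self):
        strain = np.sin(np.linspace(0, 2 * np.pi, 200))
        pressure = np.full(200, 50.0)
        assert loop_work(pressure, strain) == pytest.approx(0.0, abs=1e-9)

    def test_healthy_work_near_target(self):
        lvp, seg = simulate_pressure_strain(REFERENCE_PARAMS["baseline"], n_cycles=1,
                                            seed=0, noise=NoiseConfig.NOISELESS)
        w = loop_work(lvp, strain_from_lengths(seg, 0))
        assert w == pytest.approx(850.0, rel=0.25)

    def test_ischemic_work_below_healthy(self):
        lvp_h, seg_h = simulate_pressure_strain(REFERENCE_PARAMS["baseline"],
                                                n_cycles=1, seed=3,
                                                noise=NoiseConfig.NOISELESS)
        lvp_i, seg_i = simulate_pressure_strain(REFERENCE_PARAMS["ischemia"],
                                                n_cycles=1, seed=3,
                                                noise=NoiseConfig.NOISELESS)
        w_h = loop_work(lvp_h, strain_from_lengths(seg_h, 0))
        w_i = loop_work(lvp_i, strain_from_lengths(seg_i, 0))
        assert w_i < w_h

    def test_ischemic_morphology(self):
        """Ischemic segments lengthen during isovolumic contraction and show
        post-systolic peak shortening."""
        params = REFERENCE_PARAMS["ischemia"]
        lvp, seg = simulate_pressure_strain(params, n_cycles=1, seed=0,
                                            noise=NoiseConfig.NOISELESS)
        strain = strain_from_lengths(seg, 0)
        es_idx = int(np.argmin(np.gradient(lvp)))  # dP/dt_min sample
        assert strain[: es_idx // 2].max() > 0.0  # early lengthening
        assert int(np.argmin(strain)) > es_idx  # shortening peaks post-systole

    def test_extreme_work_target_caps_strain(self):
        """A work target implying strain below -100% (non-positive segment
        length) is capped at +-95% with a warning instead of producing an
        unphysical trace."""
        params = InterventionParams("baseline", 108.0, 9.6, 6.0,
                                    work_target_mmHg_pct=50000.0)
        with pytest.warns(UserWarning, match="capping"):
            _, seg = simulate_pressure_strain(params, n_cycles=1, seed=0,
                                              noise=NoiseConfig.NOISELESS)
        assert np.all(seg > 0)

    def test_intervention_param_validation(self):
        with pytest.raises(ValueError):
            InterventionParams("baseline", 108.0, 9.6, 6.0, ischemic=True)
        with pytest.raises(ValueError):
            InterventionParams("baseline", 0.0, 9.6, 6.0)
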