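"""Rolling-shutter schedules, drive waveform, actuator tracking, imaging."""

import math

import numpy as np
import pytest

from dualsweep import (
    BeamParameters,
    CameraConfig,
    IdealActuator,
    LagActuator,
    LfaModel,
    Phantom,
    bead_fwhm,
    detect_beads,
    generate_drive_waveform,
    lfa_track,
    pixel_size,
    shutter_schedule,
    simulate_stack,
    snr_ratio_model,
    synchronization_map,
)


class TestShutterSchedule:
    def test_dual_exposure_doubles_single(self, small_camera):
        t = 0.05
        single = shutter_schedule(small_camera("single"), t)
        dual = shutter_schedule(small_camera("dual"), t)
        assert dual.per_row_exposure_s / single.per_row_exposure_s == 2.0

    def test_single_per_row_exposure_value(self):
        # oracle: 0.1 s / 2048 rows with W=1
        cam = CameraConfig(shutter_width=1, mode="single")
        sched = shutter_schedule(cam, 0.1)
        assert sched.per_row_exposure_s == pytest.approx(48.83e-6, rel=1e-3)

    def test_every_row_active_exactly_once(self, small_camera):
        sched = shutter_schedule(small_camera("dual"), 0.025)
        assert len(sched.t_on) == 64
        assert np.all(sched.t_off > sched.t_on)

    def test_dual_paired_rows_share_window(self, small_camera):
        sched = shutter_schedule(small_camera("dual", n_rows=64), 0.025)
        assert np.array_equal(sched.t_on[:32], sched.t_on[32:])
        assert np.array_equal(sched.t_off[:32], sched.t_off[32:])

    def test_exposure_conservation(self, small_camera):
        """per-row exposure x rows per shutter = W*T in both modes."""
        t, w = 0.04, 8
        for mode in ("single", "dual"):
            cam = small_camera(mode, shutter_width=w)
            sched = shutter_schedule(cam, t)
            assert sched.per_row_exposure_s * cam.rows_per_shutter == pytest.approx(
                w * t, rel=1e-12
            )

    def test_shutter_width_limits(self):
        with pytest.raises(ValueError):
            CameraConfig(n_rows=64, shutter_width=33, mode="dual")
        CameraConfig(n_rows=64, shutter_width=33, mode="single")  # fine

    def test_dual_needs_even_rows(self):
        with pytest.raises(ValueError):
            CameraConfig(n_rows=63, n_cols=63, shutter_width=4, mode="dual")


class TestDriveWaveform:
    def test_trigger_count_and_period(self):
        w = generate_drive_waveform("dual", 0.025, 0.0025, 10, 50_000, 400.0)
        assert len(w.trigger_times_s) == 10
        assert w.period_s == pytest.approx(0.0275)

    def test_position_resets_each_period(self):
        w = generate_drive_waveform("single", 0.1, 0.01, 3, 10_000, 800.0)
        period_samples = int(round(w.period_s * w.sample_rate_hz))
        starts = w.command_um[::period_samples][:3]
        assert np.all(starts == pytest.approx(0.0, abs=1e-9))

    def test_laser_gated_off_during_flyback(self):
        w = generate_drive_waveform("dual", 0.02, 0.002, 5, 50_000, 400.0)
        phase = w.time_s % w.period_s
        assert np.array_equal(w.laser_gate, phase < w.rise_time_s)
        assert not w.laser_gate.all()

    def test_insufficient_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_drive_waveform("dual", 0.025, 0.0025, 5, 100.0, 400.0)
        with pytest.raises(ValueError):
            generate_drive_waveform("dual", 0.025, 0.0025, 5, 0.0, 400.0)


class TestActuatorTracking:
    def test_ideal_actuator_zero_error(self, small_waveform):
        w = small_waveform()
        _, err = lfa_track(w, IdealActuator())
        assert np.abs(err).max() == 0.0

    def test_zero_response_time_is_ideal(self, small_waveform):
        w = small_waveform()
        _, err = lfa_track(w, LfaModel(response_time_s=0.0))
        assert np.abs(err).max() == 0.0

    def test_slower_sweep_smaller_rise_error(self):
        """Fixed amplitude: max first-rise tracking error non-increasing in T.

        Oracle: dense LTI integration at several sweep times.
        """
        lfa = LfaModel()
        maxima = []
        for rise in (0.01, 0.025, 0.05, 0.1):
            w = generate_drive_waveform("single", rise, rise / 10, 1, 200_000, 400.0)
            _, err = lfa_track(w, lfa)
            rise_mask = w.time_s < rise
            # skip the initial response transient (~response time)
            settled = rise_mask & (w.time_s > lfa.response_time_s)
            maxima.append(np.abs(err[settled]).max())
        assert all(a >= b - 1e-9 for a, b in zip(maxima, maxima[1:]))

    def test_error_linear_in_amplitude(self):
        lfa = LfaModel()
        errs = []
        for amp in (400.0, 200.0):
            w = generate_drive_waveform("single", 0.025, 0.0025, 2, 100_000, amp)
            _, err = lfa_track(w, lfa)
            errs.append(np.abs(err).max())
        assert errs[0] == pytest.approx(2 * errs[1], rel=1e-6)

    def test_unstable_parameterization_rejected(self, small_waveform):
        with pytest.raises(ValueError):
            LfaModel(damping=-0.1)
        with pytest.raises(ValueError):
            lfa_track(small_waveform(), LfaModel(natural_frequency_rad_s=-1.0))


class TestSynchronizationMap:
    def test_ideal_actuator_zero_offsets(self, small_camera, small_waveform):
        off = synchronization_map(small_waveform(), IdealActuator(), small_camera())
        assert np.abs(off).max() == 0.0

    def test_pure_lag_offset_is_slope_times_lag(self, small_camera, small_waveform):
        w = small_waveform()
        lag = 1e-4
        off = synchronization_map(w, LagActuator(lag), small_camera())
        slope = w.amplitude_um / w.rise_time_s
        interior = off[5:27]  # rows whose midpoint falls after the lag
        assert interior == pytest.approx(-slope * lag, rel=1e-6)

    def test_dual_paired_rows_equal_offsets(self, small_camera, small_waveform):
        w = small_waveform()
        off = synchronization_map(w, LfaModel(), small_camera())
        assert np.array_equal(off[:32], off[32:])

    def test_mode_mismatch_rejected(self, small_camera, small_waveform):
        with pytest.raises(ValueError):
            synchronization_map(small_waveform("single"), IdealActuator(),
                                small_camera("dual"))


def _one_bead_stack(px, mode="dual", seed=0, intensity=2e6, diameter=0.5,
                    detection_fwhm=0.83, waist=0.4, extra_offset=0.0,
                    n_rows=64, n_frames=40):
    beam = BeamParameters(waist_radius_um=waist)
    cam = CameraConfig(n_rows=n_rows, n_cols=n_rows, shutter_width=8, mode=mode)
    amp_rows = n_rows if mode == "single" else n_rows // 2
    wave = generate_drive_waveform(mode, 0.025, 0.0025, n_frames, 60_000,
                                   amp_rows * px)
    center = (n_rows // 2 * px, n_rows // 2 * px, n_frames // 2 * px)
    phantom = Phantom(
        positions_um=np.array([center]),
        intensities=np.array([intensity]),
        diameter_um=diameter,
        extents_um=(n_rows * px, n_rows * px, n_frames * px),
    )
    from dualsweep import ImmersionScaling

    return simulate_stack(
        phantom, beam, ImmersionScaling(), cam, wave, seed=seed,
        detection_fwhm_um=detection_fwhm, extra_sync_offset_um=extra_offset,
    ), cam


class TestSimulateStack:
    def test_empty_phantom_is_offset_plus_noise(self, px_water):
        from dualsweep import ImmersionScaling

        cam = CameraConfig(n_rows=64, n_cols=64, shutter_width=8, mode="dual")
        wave = generate_drive_waveform("dual", 0.025, 0.0025, 10, 60_000,
                                       32 * px_water)
        phantom = Phantom(np.empty((0, 3)), np.empty(0), 0.5,
                          (64 * px_water, 64 * px_water, 10 * px_water))
        stack = simulate_stack(phantom, BeamParameters(), ImmersionScaling(),
                               cam, wave, seed=5)
        assert stack.data.mean() == pytest.approx(cam.offset_counts, abs=0.5)
        assert stack.data.std() == pytest.approx(cam.read_noise_counts, rel=0.2)

    def test_reproducible_for_fixed_seed(self, px_water):
        a, _ = _one_bead_stack(px_water, seed=7)
        b, _ = _one_bead_stack(px_water, seed=7)
        assert np.array_equal(a.data, b.data)

    def test_axial_fwhm_is_quadrature_of_widths(self, px_water):
        """Oracle: analytic Gaussian convolution of the configured widths.

        Widths are chosen a few voxels wide so discretization bias is
        negligible; tolerance 3%.
        """
        detection, diameter, waist = 2.0, 1.0, 0.8
        stack, _ = _one_bead_stack(px_water, intensity=5e6, diameter=diameter,
                                   detection_fwhm=detection, waist=waist,
                                   n_frames=48)
        peak = detect_beads(stack.data.astype(float), threshold=1000.0,
                            min_separation=5)[0]
        m = bead_fwhm(stack.data, tuple(peak), px_water)
        sheet_fwhm = math.sqrt(2 * math.log(2)) * waist
        expected_ax = math.sqrt(sheet_fwhm**2 + detection**2 + diameter**2)
        expected_lat = math.sqrt(detection**2 + diameter**2)
        assert m.fwhm_z_um == pytest.approx(expected_ax, rel=0.03)
        assert m.fwhm_x_um == pytest.approx(expected_lat, rel=0.03)
        assert m.fwhm_y_um == pytest.approx(expected_lat, rel=0.03)

    def test_sync_error_degrades_axial_fwhm_monotonically(self, px_water):
        """Axial width non-decreasing in an imposed constant sync offset."""
        waist = 0.4
        widths = []
        for k in (0, 1, 2, 4):
            stack, _ = _one_bead_stack(px_water, intensity=5e6,
                                       extra_offset=k * waist, waist=waist)
            peak = detect_beads(stack.data.astype(float), threshold=500.0,
                                min_separation=5)[0]
            widths.append(bead_fwhm(stack.data, tuple(peak), px_water).fwhm_z_um)
        assert all(b >= a - 0.02 for a, b in zip(widths, widths[1:]))
        assert widths[-1] > widths[0]


class TestSnrRatioModel:
    def test_shot_limited_half_exposure(self):
        # oracle: sqrt(exposure ratio) analytically
        assert snr_ratio_model(1000.0, 0.0, 0.0, 0.5, 1.0) == pytest.approx(
            1 / math.sqrt(2), rel=1e-12
        )

    def test_read_noise_limit_is_exposure_ratio(self):
        assert snr_ratio_model(1e-9, 0.0, 10.0, 0.5, 1.0) == pytest.approx(
            0.5, rel=1e-6
        )

    def test_equal_exposures_unity(self):
        assert snr_ratio_model(500.0, 50.0, 2.0, 0.3, 0.3) == 1.0

    def test_ratio_bracketed_between_limits(self):
        """Dual 25 ms vs single 100 ms: ratio in [0.5, 1/sqrt(2)] everywhere."""
        e_dual = 2 * 0.025 / 2048  # per-row exposure per unit shutter width
        e_single = 0.100 / 2048
        for s in (1.0, 1e2, 1e4, 1e6):
            for b in (0.0, 10.0, 1e3):
                for r in (0.0, 1.6, 10.0):
                    if s * e_single + b * e_single + r**2 == 0:
                        continue
                    ratio = snr_ratio_model(s, b, r, e_dual, e_single)
                    assert 0.5 - 1e-9 <= ratio <= 1 / math.sqrt(2) + 1e-9

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            snr_ratio_model(0.0, 0.0, 0.0, 1.0, 1.0)
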