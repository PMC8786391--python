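"""Reconstruction pipeline: position fitting, dewarping, slow-axis
resampling, and geometric corrections."""

import math

import numpy as np
import pytest

from stripscan import (
    Bead,
    BeadPhantom,
    LinearProfile,
    LinePositionTrack,
    RawAcquisition,
    ScannerParams,
    StageParams,
    StripImage,
    correct_anisotropy,
    correct_axis_misalignment,
    dewarp_fast_axis,
    fit_line_positions,
    make_motion_profile,
    reconstruct_strip,
    resample_slow_axis,
    sample_specimen,
    simulate_strip,
)


def _affine_raw(scanner, stage, intercept, slope, n_lines=8):
    """Raw acquisition whose samples are affine in fast-axis position."""
    S = scanner.samples_per_line
    s = np.arange(S)
    u_fwd = -np.cos(np.pi * s / S) * scanner.sweep_half_width
    directions = np.ones(n_lines, dtype=np.int8)
    directions[1::2] = -1
    samples = np.empty((n_lines, S))
    for ell in range(n_lines):
        u = u_fwd if directions[ell] > 0 else -u_fwd
        samples[ell] = intercept + slope * u
    return RawAcquisition(
        samples=samples,
        trigger_times=np.arange(n_lines) / scanner.line_rate,
        directions=directions,
        encoder_x=np.zeros(n_lines),
        encoder_y=np.zeros(n_lines),
        scanner=scanner,
        stage=stage,
        meta={"mode": "strip", "origin": [0.0, 0.0]},
    )


class TestFitLinePositions:
    def test_affine_motion_recovered_exactly(self):
        y = 3.0 + 0.26 * np.arange(300)
        track = fit_line_positions(y, window_lines=15)
        np.testing.assert_allclose(track.positions, y, atol=1e-9)
        assert track.residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_parked_stage_returns_the_reading(self):
        y = np.full(200, 12.3)
        track = fit_line_positions(y, window_lines=65)
        np.testing.assert_allclose(track.positions, 12.3, atol=1e-12)

    def test_cruise_rmse_below_ten_nanometres(self, scanner_default, stage_default):
        """Quantization noise averages below 10 nm with the default window."""
        L = 2000
        t = np.arange(L) / scanner_default.line_rate
        truth = stage_default.cruise_velocity * t
        res = stage_default.encoder_resolution
        enc = np.round(truth / res) * res
        track = fit_line_positions(enc, window_lines=65)
        rmse = np.sqrt(np.mean((track.positions - truth) ** 2))
        assert rmse < 0.010

    def test_rmse_decreases_with_window_on_cruise_data(
        self, scanner_default, stage_default
    ):
        L = 3000
        t = np.arange(L) / scanner_default.line_rate
        truth = stage_default.cruise_velocity * t
        res = stage_default.encoder_resolution
        enc = np.round(truth / res) * res
        rmses = []
        for w in (9, 33, 65):
            track = fit_line_positions(enc, window_lines=w)
            rmses.append(np.sqrt(np.mean((track.positions - truth) ** 2)))
        assert rmses[0] > rmses[1] > rmses[2]

    @pytest.mark.parametrize("window", [4, 1, 999])
    def test_bad_windows_rejected(self, window):
        with pytest.raises(ValueError):
            fit_line_positions(np.zeros(100), window_lines=window)


class TestDewarpFastAxis:
    def test_constant_line_stays_constant(self, scanner_small, stage_small):
        raw = _affine_raw(scanner_small, stage_small, 5.0, 0.0)
        out = dewarp_fast_axis(raw)
        np.testing.assert_allclose(out, 5.0, atol=1e-9)

    def test_affine_scene_affine_in_pixel_index(self, scanner_small, stage_small):
        """Oracle: direct evaluation of the affine scene at pixel centers."""
        raw = _affine_raw(scanner_small, stage_small, 5.0, 2.0)
        out = dewarp_fast_axis(raw)
        K = scanner_small.pixels_per_line
        x = (np.arange(K) + 0.5 - K / 2) * scanner_small.pixel_pitch
        expected = 5.0 + 2.0 * x
        scale = np.abs(expected).max()
        for ell in range(raw.n_lines):
            np.testing.assert_allclose(
                out[ell, :, 0], expected, rtol=0, atol=1e-6 * scale
            )

    def test_output_width_is_pixels_per_line(self, scanner_small, stage_small):
        raw = _affine_raw(scanner_small, stage_small, 1.0, 1.0)
        assert dewarp_fast_axis(raw).shape == (
            raw.n_lines, scanner_small.pixels_per_line, 1
        )


class TestResampleSlowAxis:
    def test_grid_aligned_uniform_track_is_identity(self):
        rng = np.random.default_rng(3)
        N, K = 20, 16
        pitch = 0.5
        lines = rng.uniform(0, 100, size=(N, K))
        track = LinePositionTrack(
            positions=np.arange(N) * pitch, window_lines=5, residual_rms=0.0
        )
        img = resample_slow_axis(lines, track, pitch)
        # boundary rows (first/last line) are dropped, never extrapolated
        assert img.pixels.shape[0] == N - 2
        np.testing.assert_allclose(img.pixels[:, :, 0], lines[1:-1], atol=1e-12)
        assert img.origin[1] == pytest.approx(pitch)

    def test_affine_in_position_scene_resamples_affine_in_row(
        self, scanner_default, stage_default
    ):
        """Lines whose intensity is affine in true slow position must map to
        an image affine in row index, even under the acceleration ramp."""
        prof = make_motion_profile(stage_default, 500.0)
        t = np.arange(int(prof.total_duration * scanner_default.line_rate))
        pos = prof.position(t / scanner_default.line_rate)
        lines = np.tile((10.0 + 0.3 * pos)[:, None], (1, 8))
        track = LinePositionTrack(positions=pos, window_lines=65,
                                  residual_rms=0.0)
        img = resample_slow_axis(lines, track, scanner_default.pixel_pitch)
        rows = img.pixels[:, 0, 0]
        y = img.y_coords()
        expected = 10.0 + 0.3 * y
        np.testing.assert_allclose(rows, expected, rtol=1e-3)

    def test_duplicate_positions_averaged(self):
        pos = np.array([0.0, 1.0, 1.0, 2.0, 3.0, 4.0])
        lines = np.array([[0.0], [2.0], [4.0], [6.0], [9.0], [12.0]])
        track = LinePositionTrack(positions=pos, window_lines=3,
                                  residual_rms=0.0)
        img = resample_slow_axis(lines, track, 1.0)
        # nodes become (0,1,2,3,4) with values (0,3,6,9,12): affine
        np.testing.assert_allclose(img.pixels[:, 0, 0], [3.0, 6.0, 9.0],
                                   atol=1e-9)

    def test_too_few_distinct_positions_rejected(self):
        track = LinePositionTrack(positions=np.array([0.0, 1.0, 1.0, 2.0]),
                                  window_lines=3, residual_rms=0.0)
        with pytest.raises(ValueError):
            resample_slow_axis(np.zeros((4, 4)), track, 1.0)

    def test_mean_intensity_conserved_in_cruise_region(
        self, scanner_small, stage_small, single_bead_phantom_small
    ):
        prof = make_motion_profile(stage_small, 150.0)
        raw = simulate_strip(single_bead_phantom_small, scanner_small,
                             stage_small, prof)
        lines = dewarp_fast_axis(raw)
        track = fit_line_positions(raw.encoder_y, window_lines=15)
        pos = np.maximum.accumulate(track.positions)
        track = LinePositionTrack(pos, 15, track.residual_rms)
        img = resample_slow_axis(lines, track, scanner_small.pixel_pitch)
        y_lo, y_hi = 50.0, 100.0  # cruise region containing the bead
        in_rows = (pos >= y_lo) & (pos <= y_hi)
        out_rows = (img.y_coords() >= y_lo) & (img.y_coords() <= y_hi)
        mean_in = lines[in_rows].mean()
        mean_out = img.pixels[out_rows].mean()
        assert mean_out == pytest.approx(mean_in, rel=5e-3)


class TestMisalignmentCorrection:
    def _smooth_image(self, seed=1, H=80, W=80):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(seed)
        img = gaussian_filter(rng.normal(size=(H, W)), 4.0)
        img = (img - img.min()) / (img.max() - img.min())
        return StripImage(pixels=img, origin=(0.0, 0.0), pitch=1.0)

    def test_zero_angle_is_identity(self):
        s = self._smooth_image()
        out = correct_axis_misalignment(s, 0.0)
        np.testing.assert_array_equal(out.pixels, s.pixels)

    def test_point_shifts_by_dy_tan_angle(self):
        img = np.zeros((80, 80))
        img[40, 40] = 1.0
        s = StripImage(pixels=img, origin=(0.0, 0.0), pitch=1.0)
        out = correct_axis_misalignment(s, 2.0, mode="shear")
        w = out.pixels[:, :, 0]
        cx = (w * np.arange(80)[None, :]).sum() / w.sum()
        expected_shift = 40 * math.tan(math.radians(2.0))
        assert cx == pytest.approx(40.0 - expected_shift, abs=0.05)

    def test_shear_inverse_recovers_interior(self):
        s = self._smooth_image()
        out = correct_axis_misalignment(
            correct_axis_misalignment(s, 2.0), -2.0
        )
        np.testing.assert_allclose(
            out.pixels[5:-5, 5:-5], s.pixels[5:-5, 5:-5], atol=1e-3
        )

    def test_rotate_mode_round_trip(self):
        s = self._smooth_image(seed=2)
        out = correct_axis_misalignment(
            correct_axis_misalignment(s, 3.0, mode="rotate"), -3.0, mode="rotate"
        )
        np.testing.assert_allclose(
            out.pixels[10:-10, 10:-10], s.pixels[10:-10, 10:-10], atol=5e-3
        )

    def test_large_angle_rejected(self):
        s = self._smooth_image()
        with pytest.raises(ValueError):
            correct_axis_misalignment(s, 15.0)


class TestAnisotropyCorrection:
    @staticmethod
    def _gaussian_image(pitch_fast, pitch_slow, sigma=4.0, half=30.0):
        cols = np.arange(0.0, 2 * half, pitch_fast)
        rows = np.arange(0.0, 2 * half, pitch_slow)
        xx, yy = np.meshgrid(cols - half, rows - half)
        img = np.exp(-(xx ** 2 + yy ** 2) / (2 * sigma ** 2))
        return StripImage(pixels=img, origin=(0.0, 0.0), pitch=pitch_fast)

    def test_equal_pitches_is_identity(self):
        s = self._gaussian_image(1.0, 1.0)
        out = correct_anisotropy(s, 1.0, 1.0)
        np.testing.assert_array_equal(out.pixels, s.pixels)

    def test_two_to_one_anisotropy_restores_round_bead(self):
        from stripscan import detect_beads

        s = self._gaussian_image(0.5, 1.0)
        out = correct_anisotropy(s, 0.5, 1.0)
        assert out.pitch == pytest.approx(0.5)
        det = detect_beads(out, threshold=0.3)
        assert len(det) == 1
        ratio = det[0].fwhm_fast / det[0].fwhm_slow
        assert abs(ratio - 1.0) < 0.02

    def test_physical_extent_preserved(self):
        s = self._gaussian_image(0.5, 1.0)
        out = correct_anisotropy(s, 0.5, 1.0)
        extent_in = (s.pixels.shape[0] - 1) * 1.0
        extent_out = (out.pixels.shape[0] - 1) * out.pitch
        assert abs(extent_in - extent_out) <= 1.0  # within one coarse pixel


class TestEndToEnd:
    def test_round_trip_matches_direct_phantom_sampling(self, scanner_small):
        """Simulate -> reconstruct is the identity within 0.1% of peak.

        Conditions isolate the two-pass interpolation itself: slow uniform
        motion (negligible intra-line displacement) and a fine encoder
        (negligible quantization).  Quantization and intra-line blur carry
        their own bounds elsewhere.
        """
        stage = StageParams(misalignment_angle=0.0, encoder_resolution=0.001,
                            cruise_velocity=2000.0, accel_duration=0.020,
                            accel_distance=30.0)
        ph = BeadPhantom(beads=(Bead(0.0, 10.0, 4.0, 1000.0),),
                         extent=(-60, 60, -10, 30), background=10.0)
        prof = LinearProfile(velocity=10.0, total_duration=2.2)
        raw = simulate_strip(ph, scanner_small, stage, prof)
        img = reconstruct_strip(raw, window_lines=15)
        xx, yy = np.meshgrid(img.x_coords(), img.y_coords())
        expected = sample_specimen(ph, xx, yy)
        err = np.abs(img.pixels[:, :, 0] - expected) / 1000.0
        assert err.max() < 1e-3

    def test_round_trip_at_cruise_with_default_physics(self, scanner_default):
        """With 100-nm quantization and intra-line motion at full cruise
        velocity, the round trip stays within 2% of peak (the accepted
        sub-pixel blur bound)."""
        stage = StageParams(misalignment_angle=0.0)
        ph = BeadPhantom(beads=(Bead(0.0, 20.0, 5.0, 1000.0),),
                         extent=(-300, 300, -10, 50), background=10.0)
        prof = LinearProfile(velocity=stage.cruise_velocity,
                             total_duration=40.0 / stage.cruise_velocity)
        raw = simulate_strip(ph, scanner_default, stage, prof)
        img = reconstruct_strip(raw)
        xx, yy = np.meshgrid(img.x_coords(), img.y_coords())
        expected = sample_specimen(ph, xx, yy)
        err = np.abs(img.pixels[:, :, 0] - expected) / 1000.0
        assert err.max() < 0.02

    def test_noise_off_pipeline_is_deterministic(
        self, scanner_small, stage_small, single_bead_phantom_small
    ):
        prof = make_motion_profile(stage_small, 150.0)
        raws = [
            simulate_strip(single_bead_phantom_small, scanner_small,
                           stage_small, prof)
            for _ in range(2)
        ]
        imgs = [reconstruct_strip(r, window_lines=15) for r in raws]
        np.testing.assert_array_equal(imgs[0].pixels, imgs[1].pixels)
        assert imgs[0].origin == imgs[1].origin

    def test_preaverage_option_stays_close_to_default(
        self, scanner_small, stage_small, single_bead_phantom_small
    ):
        prof = make_motion_profile(stage_small, 150.0)
        raw = simulate_strip(single_bead_phantom_small, scanner_small,
                             stage_small, prof, noise="poisson", seed=4)
        a = reconstruct_strip(raw, window_lines=15)
        b = reconstruct_strip(raw, window_lines=15, preaverage_lines=True)
        # same geometry, slightly different (averaged) intensities
        assert abs(a.origin[1] - b.origin[1]) <= scanner_small.pixel_pitch
        peak = a.pixels.max()
        ya, yb = a.y_coords(), b.y_coords()
        lo = max(ya[0], yb[0]) + 2 * scanner_small.pixel_pitch
        hi = min(ya[-1], yb[-1]) - 2 * scanner_small.pixel_pitch
        ra = a.pixels[(ya >= lo) & (ya <= hi)]
        rb = b.pixels[(yb >= lo) & (yb <= hi)]
        n = min(ra.shape[0], rb.shape[0])
        assert np.abs(ra[:n] - rb[:n]).max() < 0.25 * peak
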