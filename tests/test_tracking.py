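"""Localization, z-calibration and track post-processing."""

import numpy as np
import pandas as pd
import pytest

import helixtrack as ht
from helixtrack.imaging import ImagingConfig, center_in_field, defocus_amplitude, generate_calibration_stack, render_frame, render_movie
from helixtrack.tracking import (
    CalibrationCurve,
    Track3D,
    _fit_cubic,
    fit_z_calibration,
    invert_z,
    localize_xy,
    measure_center_intensity,
    smooth_track,
    subtract_reference,
    track_movie,
)


class TestLocalizeXY:
    def test_noiseless_pixel_center_recovery_is_exact(self, imaging_noiseless):
        # (0,0) is a pixel-grid point only for odd fields; still expect ~exact
        fr = render_frame((0.0, 0.0, 0.0), imaging_noiseless)
        loc = localize_xy(fr)
        assert loc.ok
        assert loc.x_nm == pytest.approx(0.0, abs=1e-9)
        assert loc.y_nm == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("offset", [(37.3, -81.9), (79.9, 80.1), (-3.2, 151.0)])
    def test_noiseless_subpixel_recovery_below_point_one_nm(self, imaging_noiseless, offset):
        fr = render_frame((*offset, 100.0), imaging_noiseless)
        loc = localize_xy(fr)
        assert loc.ok
        assert loc.x_nm == pytest.approx(offset[0], abs=0.1)
        assert loc.y_nm == pytest.approx(offset[1], abs=0.1)

    def test_rms_error_grows_with_noise(self):
        rng = np.random.default_rng(0)

        def rms(noise_sd):
            cfg = ImagingConfig(read_noise_sd=noise_sd)
            errs = []
            for _ in range(40):
                x, y = rng.uniform(-80, 80, 2)
                loc = localize_xy(render_frame((x, y, 0.0), cfg, rng=rng))
                errs.append((loc.x_nm - x, loc.y_nm - y))
            return float(np.sqrt(np.mean(np.square(errs))))

        assert rms(0.5) < rms(4.0) < rms(16.0)

    def test_structureless_frame_is_flagged_not_raised(self):
        loc = localize_xy(np.ones((32, 32)), pixel_size=160.0)
        assert not loc.ok


class TestCenterIntensity:
    def test_uniform_frame_measures_zero(self):
        v = measure_center_intensity(np.full((32, 32), 7.0), (0.0, 0.0), pixel_size=160.0)
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_z(self, imaging_noiseless):
        lo = measure_center_intensity(render_frame((0, 0, -250.0), imaging_noiseless), (0, 0))
        hi = measure_center_intensity(render_frame((0, 0, 250.0), imaging_noiseless), (0, 0))
        assert hi > lo > 0

    def test_linear_in_spot_amplitude(self, imaging_noiseless):
        v1 = measure_center_intensity(render_frame((0, 0, 0.0), imaging_noiseless), (0, 0))
        cfg2 = ImagingConfig(
            read_noise_sd=0.0, defocus_coeffs=tuple(2 * c for c in imaging_noiseless.defocus_coeffs)
        )
        v2 = measure_center_intensity(render_frame((0, 0, 0.0), cfg2), (0, 0))
        assert v2 == pytest.approx(2 * v1)

    def test_edge_center_returns_nan(self, imaging_noiseless):
        x_half, _ = imaging_noiseless.field_extent
        v = measure_center_intensity(
            render_frame((0, 0, 0.0), imaging_noiseless), (x_half - 10.0, 0.0)
        )
        assert np.isnan(v)

    def test_invariant_to_subpixel_position(self, imaging_noiseless):
        vals = []
        for dx in np.linspace(0, 160, 7):
            fr = render_frame((dx, 0.0, 100.0), imaging_noiseless)
            loc = localize_xy(fr)
            vals.append(measure_center_intensity(fr, (loc.x_nm, loc.y_nm)))
        assert np.ptp(vals) / np.mean(vals) < 1e-6


class TestZCalibration:
    def test_noiseless_stack_recovers_generator_cubic_exactly(
        self, imaging_noiseless, calibration_noiseless
    ):
        curve = calibration_noiseless
        true = np.asarray(imaging_noiseless.defocus_coeffs) / defocus_amplitude(
            250.0, imaging_noiseless
        )
        assert np.allclose(curve.coeffs, true, rtol=1e-9, atol=1e-14)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_default_protocol_r2_above_0_99(self, imaging_default):
        stack = generate_calibration_stack(imaging_default, seed=21)
        curve = fit_z_calibration(stack)
        assert curve.r_squared >= 0.99

    def test_three_planes_rejected(self, imaging_noiseless):
        stack = generate_calibration_stack(
            imaging_noiseless, z_min=-250, z_max=250, z_step=250, n_repeats=2, seed=0
        )
        with pytest.raises(ValueError, match="4 distinct z planes"):
            fit_z_calibration(stack)

    def test_non_monotone_intensities_rejected(self):
        z = np.arange(-250.0, 251.0, 25.0)
        parabola = (z / 250.0) ** 2
        coeffs, _ = _fit_cubic(z, parabola)
        with pytest.raises(ValueError, match="monotonic"):
            CalibrationCurve(tuple(coeffs), (-250.0, 250.0), 1.0, 0.0, 1.0)

    def test_curve_json_round_trip(self, tmp_path, calibration_noiseless):
        path = tmp_path / "cal.json"
        calibration_noiseless.to_json(path)
        back = CalibrationCurve.from_json(path)
        assert back.coeffs == calibration_noiseless.coeffs
        assert back.scale == calibration_noiseless.scale


class TestInvertZ:
    def test_inverse_on_forward_values(self, calibration_noiseless):
        for z_true in (-250.0, -150.0, 0.0, 37.5, 150.0, 250.0):
            z, ok = invert_z(calibration_noiseless(z_true), calibration_noiseless)
            assert ok
            assert z == pytest.approx(z_true, abs=1e-3)

    def test_out_of_range_intensity_clamps_and_flags(self, calibration_noiseless):
        lo, hi = calibration_noiseless.intensity_range
        z, ok = invert_z(hi * 1.5, calibration_noiseless)
        assert not ok
        assert z == pytest.approx(250.0)
        z, ok = invert_z(lo - 1e-4, calibration_noiseless)  # just outside: clamped, still ok
        assert ok
        assert z == pytest.approx(-250.0)

    def test_noiseless_movie_round_trip_below_1nm(self, imaging_noiseless, calibration_noiseless):
        cfg = ht.CargoSimConfig(pitch_program=[(15.0, 600.0, "right")], noise_sd_xyz=(0, 0, 0))
        traj = center_in_field(ht.simulate_cargo(cfg, seed=3), imaging_noiseless)
        movie = render_movie(traj, imaging_noiseless, seed=0)
        track = track_movie(movie, calibration_noiseless)
        assert track.valid.all()
        err = track.z_nm - traj.true_z_nm
        assert np.sqrt(np.mean(err**2)) < 1.0
        exy = np.hypot(track.x_nm - traj.true_x_nm, track.y_nm - traj.true_y_nm)
        assert exy.max() < 0.5

    def test_normalization_choice_does_not_change_z(self, imaging_noiseless, calibration_noiseless):
        # a movie spanning the full z range: per-movie-max normalization and
        # calibration-scale normalization must agree
        cfg = ht.CargoSimConfig(pitch_program=[(10.0, 600.0, "right")], noise_sd_xyz=(0, 0, 0))
        traj = center_in_field(ht.simulate_cargo(cfg, seed=5), imaging_noiseless)
        movie = render_movie(traj, imaging_noiseless, seed=0)
        za = track_movie(movie, calibration_noiseless, normalization="calibration").z_nm
        zb = track_movie(movie, calibration_noiseless, normalization="movie_max").z_nm
        assert np.allclose(za, zb, atol=0.5)


class TestSmoothTrack:
    def _track(self, x):
        x = np.asarray(x, dtype=float)
        return Track3D(
            time_s=np.arange(len(x), dtype=float),
            x_nm=x,
            y_nm=np.zeros_like(x),
            z_nm=np.zeros_like(x),
            intensity=np.zeros_like(x),
            valid=np.ones(len(x), dtype=bool),
        )

    def test_constant_track_unchanged(self):
        tr = smooth_track(self._track(np.full(20, 3.5)), window=5)
        assert np.allclose(tr.x_nm, 3.5)

    def test_window_one_is_identity(self):
        t = self._track(np.arange(10.0))
        assert np.array_equal(smooth_track(t, window=1).x_nm, t.x_nm)

    def test_unit_impulse_spreads_to_fifth(self):
        x = np.zeros(11)
        x[5] = 1.0
        sm = smooth_track(self._track(x), window=5)
        assert np.allclose(sm.x_nm[3:8], 0.2)
        assert np.allclose(sm.x_nm[:3], 0.0) and np.allclose(sm.x_nm[8:], 0.0)

    def test_flagged_frames_excluded_from_average(self):
        t = self._track(np.ones(9))
        t.x_nm[4] = 100.0
        t.valid[4] = False
        sm = smooth_track(t, window=3)
        assert np.allclose(sm.x_nm[[3, 5]], 1.0)  # outlier not mixed in
        assert sm.x_nm[4] == 100.0  # flagged value passed through unsmoothed

    def test_even_or_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_track(self._track(np.zeros(10)), window=4)
        with pytest.raises(ValueError):
            smooth_track(self._track(np.zeros(3)), window=5)

    def test_preserves_mean_of_stationary_segment(self):
        rng = np.random.default_rng(2)
        x = rng.normal(5.0, 1.0, 501)
        sm = smooth_track(self._track(x), window=5)
        assert sm.x_nm[50:-50].mean() == pytest.approx(x[50:-50].mean(), abs=0.05)


class TestSubtractReference:
    def _track(self, y, x=None):
        y = np.asarray(y, dtype=float)
        return Track3D(
            time_s=np.arange(len(y)) * 0.1,
            x_nm=np.zeros_like(y) if x is None else np.asarray(x, float),
            y_nm=y,
            z_nm=np.zeros_like(y),
            intensity=np.zeros_like(y),
            valid=np.ones(len(y), dtype=bool),
        )

    def test_reference_equal_to_trace_zeroes_perpendicular(self):
        y = np.sin(np.arange(50) * 0.3) * 30
        ref = pd.DataFrame({"time_s": np.arange(50) * 0.1, "perp_nm": y, "par_nm": np.zeros(50)})
        out = subtract_reference(self._track(y), ref)
        assert np.allclose(out.y_nm, 0.0)

    def test_exact_fluctuation_subtraction_recovers_clean_helix(self):
        fluct = ht.simulate_bridge_fluctuation(35.0, 17.0, 201, seed=3)
        cfg = ht.CargoSimConfig(
            pitch_program=[(20.0, 600.0, "right")], orbit_radius=50.0, noise_sd_xyz=(0, 0, 0)
        )
        clean = ht.simulate_cargo(cfg, seed=1)
        noisy = self._track(clean.y_nm + fluct["perp_nm"].to_numpy())
        out = subtract_reference(noisy, fluct)
        assert np.allclose(out.y_nm, clean.y_nm)

    def test_zero_reference_is_identity(self):
        y = np.arange(20.0)
        ref = pd.DataFrame({"time_s": np.arange(20) * 0.1, "perp_nm": np.zeros(20)})
        out = subtract_reference(self._track(y), ref)
        assert np.array_equal(out.y_nm, y)

    def test_non_overlapping_time_ranges_rejected(self):
        ref = pd.DataFrame({"time_s": np.arange(10) * 0.1 + 100.0, "perp_nm": np.zeros(10)})
        with pytest.raises(ValueError, match="overlap"):
            subtract_reference(self._track(np.zeros(10)), ref)


def test_all_flagged_movie_warns_and_yields_empty_track(imaging_noiseless, calibration_noiseless):
    movie = ht.Movie(
        frames=np.full((12, 32, 32), 50.0),
        time_s=np.arange(12.0),
        config=ImagingConfig(shape=(32, 32), read_noise_sd=0.0),
    )
    with pytest.warns(UserWarning, match="all frames flagged"):
        track = track_movie(movie, calibration_noiseless)
    assert not track.valid.any()
    assert len(track) == 12
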