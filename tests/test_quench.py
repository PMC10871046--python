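"""Quench calibration, FTT signature projection and dip statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fttclean as f
from fttclean.bioheat import TemperatureMovie
from fttclean.quench import (
    DegenerateDesignError,
    UndefinedCorrelationError,
    ftt_signature,
    mean_ftt_dip,
)


class TestAffineQuenchFit:
    def test_exact_line(self):
        cal = f.fit_affine_quench([20, 30, 40], [100, 95, 90])
        assert cal.slope == pytest.approx(-0.5, abs=1e-12)
        assert cal.intercept == pytest.approx(110.0, abs=1e-9)
        assert cal.fit_residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_two_points_interpolate(self):
        cal = f.fit_affine_quench([25.0, 35.0], [98.0, 92.0])
        assert cal.slope == pytest.approx(-0.6)
        assert cal.fit_residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_matches_polyfit(self):
        rng = np.random.default_rng(0)
        T = np.linspace(20, 45, 12)
        F = 105 - 1.3 * T + rng.normal(0, 0.5, 12)
        cal = f.fit_affine_quench(T, F)
        slope, intercept = np.polyfit(T, F, 1)
        assert cal.slope == pytest.approx(slope, rel=1e-9)
        assert cal.intercept == pytest.approx(intercept, rel=1e-9)

    @given(
        st.lists(st.floats(min_value=0.1, max_value=5.0), min_size=2, max_size=8),
    )
    @settings(deadline=None, max_examples=50)
    def test_decreasing_brightness_gives_negative_slope(self, drops):
        T = np.arange(len(drops) + 1, dtype=float) * 2.0 + 20.0
        F = 100.0 - np.concatenate([[0.0], np.cumsum(drops)])
        assert f.fit_affine_quench(T, F).slope < 0

    def test_identical_temperatures_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            f.fit_affine_quench([30.0, 30.0, 30.0], [99.0, 98.0, 97.0])


def _toy_temperature_movie(n_t=10, n=21, h=50e-6, sigma=200e-6):
    """Separable DT = g(t) * Gaussian(x, y, z) with a known focal trace."""
    ax = (np.arange(n) - n // 2) * h
    g = np.sin(np.linspace(0.1, np.pi, n_t)) ** 2
    blob = np.exp(-0.5 * (ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2) / sigma**2)
    values = g[:, None, None, None] * blob[None]
    times = np.arange(n_t) * 0.04
    return TemperatureMovie(x=ax, y=ax, z=ax, times=times, values=values.astype(np.float32)), g


class TestFttSignature:
    camera = f.CameraGeometry(n_rows=17, n_cols=17, pixel_pitch=50e-6, focus_pixel=(8, 8))

    def test_zero_temperature_zero_signature(self, cal):
        movie, _ = _toy_temperature_movie()
        movie.values = np.zeros_like(movie.values)
        sig = ftt_signature(movie, cal, self.camera)
        assert np.all(sig.values == 0.0)

    def test_focal_pixel_follows_negative_temperature(self):
        movie, g = _toy_temperature_movie()
        unit = f.QuenchCalibration(slope=-1.0, intercept=0.0)
        sig = ftt_signature(movie, unit, self.camera)
        np.testing.assert_allclose(sig.values[:, 8, 8], -g, rtol=1e-5, atol=1e-6)

    def test_signature_scales_with_temperature(self, cal):
        movie, _ = _toy_temperature_movie()
        sig1 = ftt_signature(movie, cal, self.camera)
        movie.values = 2.0 * movie.values
        sig2 = ftt_signature(movie, cal, self.camera)
        np.testing.assert_allclose(sig2.values, 2.0 * sig1.values, rtol=1e-5)

    def test_zero_outside_simulated_extent(self, cal):
        movie, _ = _toy_temperature_movie(n=9)  # grid much smaller than camera
        sig = ftt_signature(movie, cal, self.camera)
        assert np.all(sig.values[:, 0, :] == 0.0)
        assert np.all(sig.values[:, :, 0] == 0.0)

    def test_unknown_projection_rejected(self, cal):
        movie, _ = _toy_temperature_movie()
        with pytest.raises(ValueError, match="projection"):
            ftt_signature(movie, cal, self.camera, projection="bogus")

    def test_depth_weighted_bounded_by_focal_plane_peak(self, cal):
        movie, _ = _toy_temperature_movie()
        focal = ftt_signature(movie, cal, self.camera, projection="focal_plane")
        weighted = ftt_signature(movie, cal, self.camera, projection="depth_weighted")
        # a depth average over the blob can only quench less than its core
        assert weighted.values.min() >= focal.values.min()


def test_forward_signature_scales_with_intensity(small_scfg, medium, props, cal):
    camera = f.CameraGeometry(n_rows=17, n_cols=17, pixel_pitch=88e-6, focus_pixel=(8, 8))
    lo = f.simulate_ftt_signature(
        f.SonicationConfig(peak_pressure=2.5e6, n_stimuli=5, inter_stimulus_interval=4.0),
        medium, props, cal, camera, t_end=0.5,
    )
    hi = f.simulate_ftt_signature(
        f.SonicationConfig(peak_pressure=2.8e6, n_stimuli=5, inter_stimulus_interval=4.0),
        medium, props, cal, camera, t_end=0.5,
    )
    np.testing.assert_allclose(hi.values, lo.values * (2.8 / 2.5) ** 2, rtol=1e-5)
    assert hi.values.min() < 0  # quenching, not brightening


class TestMeanFttDip:
    times = np.arange(20) * 0.04

    def test_constant_dip(self):
        trace = np.full(20, -2.0)
        assert mean_ftt_dip(trace, self.times, (0.0, 0.15)) == pytest.approx(-2.0)

    def test_zero_trace(self):
        assert mean_ftt_dip(np.zeros(20), self.times, (0.0, 0.15)) == 0.0

    def test_linear_ramp_mean(self):
        # ramp 0 -> -3 across the window samples averages to -1.5
        trace = np.zeros(20)
        trace[:5] = np.linspace(0.0, -3.0, 5)
        assert mean_ftt_dip(trace, self.times, (0.0, 0.16)) == pytest.approx(-1.5)

    def test_ignores_outside_window(self):
        a = np.full(20, -2.0)
        b = a.copy()
        b[10:] = 99.0
        w = (0.0, 0.15)
        assert mean_ftt_dip(a, self.times, w) == mean_ftt_dip(b, self.times, w)

    def test_window_outside_support(self):
        with pytest.raises(ValueError):
            mean_ftt_dip(np.zeros(20), self.times, (0.5, 2.0))


class TestDipIntensityCorrelation:
    def test_proportional_is_perfectly_anticorrelated(self):
        I = np.array([1.0, 2.0, 3.0, 4.0])
        assert f.dip_intensity_correlation(-0.5 * I, I) == pytest.approx(-1.0)

    def test_orthogonal_pattern_uncorrelated(self):
        # symmetric (+d, -d, -d, +d) against odd-symmetric intensity deviations
        I = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.array([0.3, -0.3, -0.3, 0.3]) - 1.0
        assert f.dip_intensity_correlation(d, I) == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_rolled_pearson(self):
        rng = np.random.default_rng(2)
        I = np.linspace(1, 2, 9)
        d = -I + rng.normal(0, 0.2, 9)
        r = f.dip_intensity_correlation(d, I)
        dc, Ic = d - d.mean(), I - I.mean()
        expected = float(np.sum(dc * Ic) / np.sqrt(np.sum(dc**2) * np.sum(Ic**2)))
        assert r == pytest.approx(expected, rel=1e-9)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            f.dip_intensity_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
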