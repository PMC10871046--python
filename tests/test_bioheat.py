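"""Pennes solver against closed-form oracles (heat kernel, exponential decay)."""

import numpy as np
import pytest

import fttclean as f
from fttclean.acoustic import IntensityField3D, OutOfBoundsError
from fttclean.bioheat import StabilityError, simulate_bioheat, sample_timecourse

NO_PERFUSION = f.ThermalProperties(perfusion_time_constant=np.inf)


def zero_field(x, y, z):
    return IntensityField3D(x=x, y=y, z=z, values=np.zeros((len(x), len(y), len(z))))


def axes(half, h):
    n = int(round(half / h))
    ax = np.arange(-n, n + 1) * h
    return ax, ax, ax


def gaussian_ic(x, y, z, sigma, amp=1.0):
    gx = np.exp(-0.5 * (x / sigma) ** 2)
    gy = np.exp(-0.5 * (y / sigma) ** 2)
    gz = np.exp(-0.5 * (z / sigma) ** 2)
    return amp * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]


def test_zero_source_stays_zero(props):
    x, y, z = axes(0.5e-3, 1e-4)
    movie = simulate_bioheat(zero_field(x, y, z), props, 0.1, 0.3, 0.05)
    assert np.all(movie.values == 0.0)


def test_gaussian_spreads_like_heat_kernel():
    """Source-free diffusion of a Gaussian: variance grows by 2*alpha*t."""
    props = NO_PERFUSION
    alpha = props.diffusivity
    sigma0 = 0.25e-3
    t_end = 0.3
    x, y, z = axes(1.4e-3, 70e-6)
    ic = gaussian_ic(x, y, z, sigma0)
    movie = simulate_bioheat(
        zero_field(x, y, z), props, 0.0, t_end, 0.05, initial_temperature=ic
    )
    sig_t = np.sqrt(sigma0**2 + 2.0 * alpha * t_end)
    amp = (sigma0**2 / sig_t**2) ** 1.5
    expected = gaussian_ic(x, y, z, sig_t, amp)
    got = movie.values[-1].astype(np.float64)
    rel_l2 = np.linalg.norm(got - expected) / np.linalg.norm(expected)
    assert rel_l2 < 0.02


def test_perfusion_only_exponential_decay():
    """kappa -> 0 with finite tau: interior decays as exp(-t/tau)."""
    tau = 2.0
    props = f.ThermalProperties(thermal_conductivity=1e-12, perfusion_time_constant=tau)
    x, y, z = axes(0.5e-3, 1e-4)
    ic = np.ones((len(x), len(y), len(z)))
    movie = simulate_bioheat(zero_field(x, y, z), props, 0.0, 1.0, 0.04, initial_temperature=ic)
    centre = movie.values[:, 5, 5, 5].astype(np.float64)
    # exact against the discrete recursion, and within a percent of exp
    dt_int = 0.04  # tau/50 cap
    n = np.arange(len(movie.times))
    np.testing.assert_allclose(centre, (1.0 - dt_int / tau) ** n, rtol=1e-5)
    np.testing.assert_allclose(centre, np.exp(-movie.times / tau), rtol=1e-2)


def test_linearity_and_superposition(props):
    x, y, z = axes(0.6e-3, 75e-6)
    rng = np.random.default_rng(0)
    a = IntensityField3D(x=x, y=y, z=z, values=rng.random((len(x),) * 3) * 1e6)
    b = IntensityField3D(x=x, y=y, z=z, values=rng.random((len(x),) * 3) * 1e6)
    ab = IntensityField3D(x=x, y=y, z=z, values=a.values + b.values)
    kw = dict(pulse_duration=0.1, t_end=0.3, dt=0.05)
    sa = simulate_bioheat(a, props, **kw).values.astype(np.float64)
    sb = simulate_bioheat(b, props, **kw).values.astype(np.float64)
    sab = simulate_bioheat(ab, props, **kw).values.astype(np.float64)
    scale = np.max(np.abs(sab))
    assert np.max(np.abs(sa + sb - sab)) / scale < 1e-6
    a2 = IntensityField3D(x=x, y=y, z=z, values=2.0 * a.values)
    sa2 = simulate_bioheat(a2, props, **kw).values.astype(np.float64)
    assert np.max(np.abs(sa2 - 2.0 * sa)) / np.max(np.abs(sa2)) < 1e-6


def test_maximum_principle_nonnegative(props):
    x, y, z = axes(0.6e-3, 75e-6)
    rng = np.random.default_rng(1)
    field = IntensityField3D(x=x, y=y, z=z, values=rng.random((len(x),) * 3) * 1e6)
    movie = simulate_bioheat(field, props, 0.1, 0.4, 0.05)
    assert movie.values.min() >= 0.0


def test_energy_conserved_without_perfusion():
    """tau = inf, source off: the spatial integral of DT is conserved."""
    x, y, z = axes(1.2e-3, 60e-6)
    ic = gaussian_ic(x, y, z, 0.15e-3)
    movie = simulate_bioheat(
        zero_field(x, y, z), NO_PERFUSION, 0.0, 0.2, 0.05, initial_temperature=ic
    )
    totals = movie.values.astype(np.float64).sum(axis=(1, 2, 3))
    assert abs(totals[-1] / totals[0] - 1.0) < 0.01


@pytest.fixture(scope="module")
def focal_movie(props):
    scfg = f.SonicationConfig(focal_fwhm_lateral=200e-6, focal_fwhm_axial=600e-6)
    h = 40e-6
    x = np.arange(-55, 56) * h  # spans 10 lateral FWHM
    y = np.arange(-15, 16) * h
    z = np.arange(-10, 11) * 120e-6
    field = f.focal_intensity_field(scfg, f.Medium(), x, y, z)
    return simulate_bioheat(field, props, scfg.pulse_duration, 0.5, 0.025)


class TestFocalTimecourse:
    def test_focal_rise_peak_decay(self, focal_movie):
        trace = sample_timecourse(focal_movie, (0.0, 0.0, 0.0))
        i_pulse_end = 6  # 0.15 s at 25 ms sampling
        assert np.all(np.diff(trace[: i_pulse_end + 1]) > 0)
        assert int(np.argmax(trace)) == i_pulse_end
        assert np.all(np.diff(trace[i_pulse_end:]) < 0)

    def test_off_focus_peak_is_later(self, focal_movie):
        focal = sample_timecourse(focal_movie, (0.0, 0.0, 0.0))
        off = sample_timecourse(focal_movie, (400e-6, 0.0, 0.0))  # 2 FWHM away
        assert int(np.argmax(off)) > int(np.argmax(focal))

    def test_far_field_stays_cold(self, focal_movie):
        focal = sample_timecourse(focal_movie, (0.0, 0.0, 0.0))
        far = sample_timecourse(focal_movie, (2.0e-3, 0.0, 0.0))  # 10 FWHM
        assert far.max() < 0.01 * focal.max()

    def test_doubling_source_doubles_timecourse(self, props):
        scfg1 = f.SonicationConfig(peak_pressure=2.0e6)
        scfg2 = f.SonicationConfig(peak_pressure=2.0e6 * np.sqrt(2.0))
        h = scfg1.focal_fwhm_lateral / 5
        x = np.arange(-10, 11) * h
        z = np.arange(-6, 7) * scfg1.focal_fwhm_axial / 5
        m1 = simulate_bioheat(
            f.focal_intensity_field(scfg1, f.Medium(), x, x, z), props, 0.1, 0.3, 0.05
        )
        m2 = simulate_bioheat(
            f.focal_intensity_field(scfg2, f.Medium(), x, x, z), props, 0.1, 0.3, 0.05
        )
        t1 = sample_timecourse(m1, (0, 0, 0))
        t2 = sample_timecourse(m2, (0, 0, 0))
        np.testing.assert_allclose(t2, 2.0 * t1, rtol=1e-5)


def test_forced_unstable_step_raises(props):
    x, y, z = axes(0.5e-3, 1e-4)
    from fttclean.bioheat import _stability_bound

    bound = _stability_bound(props.diffusivity, (1e-4, 1e-4, 1e-4), props.perfusion_time_constant)
    with pytest.raises(StabilityError, match="bound"):
        simulate_bioheat(zero_field(x, y, z), props, 0.1, 0.3, 0.05, internal_dt=1.5 * bound)


def test_sample_outside_grid_raises(props):
    x, y, z = axes(0.5e-3, 1e-4)
    movie = simulate_bioheat(zero_field(x, y, z), props, 0.1, 0.3, 0.05)
    with pytest.raises(OutOfBoundsError):
        sample_timecourse(movie, (1.0, 0.0, 0.0))
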