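"""Temperature-to-fluorescence transduction and the fluoro-thermal tag (FTT).

GCaMP-class indicators dim reversibly as tissue warms; over the few-kelvin
range relevant here the brightness-temperature relation is affine with a
negative slope.  This module fits that calibration from bath measurements,
converts a simulated temperature movie into the predicted spatio-temporal
fluorescence signature of the thermal transient (the "FTT"), and provides
the dip statistics used for the dose-response readout (mean dip during the
sonication window versus acoustic intensity).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

from .acoustic import (
    Medium,
    SonicationConfig,
    focal_intensity_field,
    fwhm_to_sigma,
    pressure_to_intensity,
)
from .bioheat import TemperatureMovie, ThermalProperties, simulate_bioheat

__all__ = [
    "QuenchCalibration",
    "CameraGeometry",
    "FTTSignature",
    "DegenerateDesignError",
    "UndefinedCorrelationError",
    "fit_affine_quench",
    "ftt_signature",
    "mean_ftt_dip",
    "dip_intensity_correlation",
    "simulate_ftt_signature",
    "focal_dip_profile",
]


class DegenerateDesignError(ValueError):
    """Raised when a calibration fit has no temperature spread."""


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested for a constant input vector."""


@dataclass(frozen=True)
class QuenchCalibration:
    """Affine brightness-temperature calibration.

    ``slope`` is in percent dF/F0 per kelvin (negative for thermal
    quenching), ``intercept`` in percent, ``fit_residual_rms`` the RMS of
    the fit residuals in percent.
    """

    slope: float
    intercept: float
    fit_residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("calibration slope must be finite")


@dataclass(frozen=True)
class CameraGeometry:
    """Widefield camera plane: pixel grid, pitch and the focus pixel."""

    n_rows: int
    n_cols: int
    pixel_pitch: float  # m
    focus_pixel: tuple[int, int]  # (row, col)

    def __post_init__(self) -> None:
        r, c = self.focus_pixel
        if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
            raise ValueError(f"focus_pixel {self.focus_pixel} outside camera grid")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")


@dataclass
class FTTSignature:
    """Predicted fluorescence change of the thermal transient.

    ``values`` is (n_times, n_rows, n_cols) in percent dF/F0 on the camera
    pixel grid; ``times`` is seconds from sonication onset.  The minimum
    (deepest quench) occurs at/near ``focus_pixel`` during the pulse, and
    values relax to zero with the thermal decay.
    """

    times: np.ndarray
    values: np.ndarray
    focus_pixel: tuple[int, int]


def fit_affine_quench(temperatures, fluorescence) -> QuenchCalibration:
    """Ordinary least-squares affine fit of brightness (percent) vs temperature (K).

    Requires at least two distinct temperatures; raises
    ``DegenerateDesignError`` when all temperatures coincide.
    """
    T = np.asarray(temperatures, dtype=float)
    F = np.asarray(fluorescence, dtype=float)
    if T.shape != F.shape or T.ndim != 1 or len(T) < 2:
        raise ValueError("need >= 2 paired (temperature, fluorescence) samples")
    if np.ptp(T) == 0:
        raise DegenerateDesignError("all temperatures identical; slope undefined")
    A = np.column_stack([T, np.ones_like(T)])
    (slope, intercept), *_ = np.linalg.lstsq(A, F, rcond=None)
    resid = F - (slope * T + intercept)
    rms = float(np.sqrt(np.mean(resid**2)))
    return QuenchCalibration(slope=float(slope), intercept=float(intercept), fit_residual_rms=rms)


def ftt_signature(
    movie: TemperatureMovie,
    cal: QuenchCalibration,
    camera: CameraGeometry,
    *,
    projection: str = "focal_plane",
    focus_position: tuple[float, float, float] = (0.0, 0.0, 0.0),
    attenuation_length: float = 500e-6,
) -> FTTSignature:
    """Project a temperature movie onto the camera plane as percent dF/F0.

    Each voxel maps through the calibration slope alone (dF/F0 = slope * DT;
    baseline-referenced data have zero offset, so the intercept is ignored).
    The 3-D to 2-D projection is either ``"focal_plane"`` (the x-y plane
    through the focus depth, default) or ``"depth_weighted"`` (exponential
    optical weighting along z with the given attenuation length).  The
    projected map is resampled bilinearly onto the camera pixel grid,
    centred so that the focus lands on ``camera.focus_pixel``; pixels
    outside the simulated extent are zero.
    """
    fx, fy, fz = focus_position
    if projection == "focal_plane":
        # linear interpolation along z at the focus depth
        iz = int(np.searchsorted(movie.z, fz))
        iz = min(max(iz, 1), len(movie.z) - 1)
        z0, z1 = movie.z[iz - 1], movie.z[iz]
        w = (fz - z0) / (z1 - z0)
        planes = (1 - w) * movie.values[:, :, :, iz - 1] + w * movie.values[:, :, :, iz]
    elif projection == "depth_weighted":
        # camera looks along -z; shallower voxels weigh more
        wz = np.exp(-(movie.z - movie.z[0]) / attenuation_length)
        wz = wz / wz.sum()
        planes = np.tensordot(movie.values, wz, axes=([3], [0]))
    else:
        raise ValueError(f"unknown projection mode {projection!r}")

    r0, c0 = camera.focus_pixel
    rows = (np.arange(camera.n_rows) - r0) * camera.pixel_pitch + fx
    cols = (np.arange(camera.n_cols) - c0) * camera.pixel_pitch + fy
    RR, CC = np.meshgrid(rows, cols, indexing="ij")
    pts = np.column_stack([RR.ravel(), CC.ravel()])

    out = np.zeros((len(movie.times), camera.n_rows, camera.n_cols), dtype=np.float32)
    for i, plane in enumerate(planes):
        interp = RegularGridInterpolator(
            (movie.x, movie.y), plane, bounds_error=False, fill_value=0.0
        )
        out[i] = (cal.slope * interp(pts)).reshape(camera.n_rows, camera.n_cols)
    return FTTSignature(times=movie.times.copy(), values=out, focus_pixel=(r0, c0))


def mean_ftt_dip(trace, times, sonication_window) -> float:
    """Mean of a dF/F0 trace over the sonication window [t0, t1] (percent).

    This is the dose-response readout: for a thermally driven dip it scales
    with the deposited acoustic intensity.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(trace, dtype=float)
    t0, t1 = sonication_window
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError(f"window [{t0}, {t1}] outside trace support [{t[0]}, {t[-1]}]")
    mask = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    if not np.any(mask):
        raise ValueError(f"window [{t0}, {t1}] contains no samples")
    return float(np.mean(y[mask]))


def dip_intensity_correlation(dips, intensities) -> float:
    """Sample Pearson correlation between mean FTT dips and acoustic intensities."""
    d = np.asarray(dips, dtype=float)
    I = np.asarray(intensities, dtype=float)
    if d.shape != I.shape or d.ndim != 1 or len(d) < 3:
        raise ValueError("need >= 3 paired (dip, intensity) observations")
    if np.ptp(d) == 0 or np.ptp(I) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(d, I).statistic)


# ---------------------------------------------------------------------------
# forward model convenience: sonication config -> FTT signature on the camera

@lru_cache(maxsize=4)
def _unit_temperature_movie(
    scfg: SonicationConfig,
    medium: Medium,
    props: ThermalProperties,
    t_end: float,
    dt: float,
) -> TemperatureMovie:
    """Bioheat solution for a 1 MPa reference pulse, cached.

    The Pennes equation is linear in the source, so the temperature movie
    for any pressure is this reference scaled by the intensity ratio; the
    cache is keyed on the focal geometry and thermal inputs with the
    pressure normalised out.
    """
    ref = SonicationConfig(
        carrier_frequency=scfg.carrier_frequency,
        peak_pressure=1e6,  # reference; rescaled by the caller
        pulse_duration=scfg.pulse_duration,
        focus_position=scfg.focus_position,
        focal_fwhm_lateral=scfg.focal_fwhm_lateral,
        focal_fwhm_axial=scfg.focal_fwhm_axial,
        inter_stimulus_interval=scfg.inter_stimulus_interval,
        n_stimuli=scfg.n_stimuli,
    )
    s_lat = fwhm_to_sigma(ref.focal_fwhm_lateral)
    s_ax = fwhm_to_sigma(ref.focal_fwhm_axial)
    diff_len = np.sqrt(2.0 * props.diffusivity * t_end)
    half_lat = 4.0 * s_lat + 2.5 * diff_len
    half_ax = 4.0 * s_ax + 2.5 * diff_len
    h_lat = ref.focal_fwhm_lateral / 5.0
    h_ax = ref.focal_fwhm_axial / 5.0
    fx, fy, fz = ref.focus_position
    nx = int(np.ceil(half_lat / h_lat))
    nz = int(np.ceil(half_ax / h_ax))
    x = fx + np.arange(-nx, nx + 1) * h_lat
    y = fy + np.arange(-nx, nx + 1) * h_lat
    z = fz + np.arange(-nz, nz + 1) * h_ax

    field = focal_intensity_field(ref, medium, x, y, z)
    return simulate_bioheat(field, props, ref.pulse_duration, t_end, dt)


def _pressure_scale(scfg: SonicationConfig, medium: Medium) -> float:
    return pressure_to_intensity(scfg.peak_pressure, medium) / pressure_to_intensity(1e6, medium)


def simulate_ftt_signature(
    scfg: SonicationConfig,
    medium: Medium,
    props: ThermalProperties,
    cal: QuenchCalibration,
    camera: CameraGeometry,
    *,
    t_end: float = 3.0,
    dt: float = 0.04,
    projection: str = "focal_plane",
) -> FTTSignature:
    """Run the acoustic + bioheat + quench forward model for one sonication.

    Returns the predicted percent-dF/F0 FTT movie on the camera grid, from
    sonication onset to ``t_end`` at step ``dt``.  Thanks to the linearity
    of the bioheat equation the heavy simulation is cached per geometry and
    rescaled analytically for pressure; only the cheap camera projection is
    redone per focus pixel.
    """
    tmovie = _unit_temperature_movie(scfg, medium, props, float(t_end), float(dt))
    sig = ftt_signature(
        tmovie, cal, camera, projection=projection, focus_position=scfg.focus_position
    )
    sig.values *= np.float32(_pressure_scale(scfg, medium))
    return sig


def focal_dip_profile(
    scfg: SonicationConfig,
    medium: Medium,
    props: ThermalProperties,
    cal: QuenchCalibration,
    *,
    t_end: float = 3.0,
    dt: float = 0.04,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted dF/F0 time course at the focus (times, percent).

    Camera-independent: used e.g. as the temporal template when localising
    the observed dip.
    """
    from .bioheat import sample_timecourse

    tmovie = _unit_temperature_movie(scfg, medium, props, float(t_end), float(dt))
    trace = sample_timecourse(tmovie, scfg.focus_position)
    return tmovie.times.copy(), cal.slope * _pressure_scale(scfg, medium) * trace
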