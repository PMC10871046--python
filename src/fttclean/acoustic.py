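"""Parametric model of the focused-ultrasound focal field and pressure-derived scalars.

The transducer array itself is not simulated.  The focal intensity
distribution is represented by a separable anisotropic Gaussian ellipsoid
whose lateral and axial full-widths at half maximum are taken from
measurement (350 um lateral focal spots are achievable through the intact
mouse skull at 3 MHz).  The bioheat solver consumes only this intensity
distribution, so the parametric surrogate is sufficient for predicting the
thermal transient.

Internal units are SI throughout (Hz, Pa, m, W/m^2).  Megapascals and
megahertz appear only at the mechanical-index interface, where the index is
conventionally defined on those units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Medium",
    "SonicationConfig",
    "IntensityField3D",
    "InvalidMediumError",
    "InvalidFrequencyError",
    "OutOfBoundsError",
    "pressure_to_intensity",
    "mechanical_index",
    "focal_intensity_field",
    "fwhm_to_sigma",
]

#: conversion between full-width at half maximum and Gaussian sigma
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


class InvalidMediumError(ValueError):
    """Raised when an acoustic medium has non-physical properties."""


class InvalidFrequencyError(ValueError):
    """Raised when a carrier frequency is not strictly positive."""


class OutOfBoundsError(ValueError):
    """Raised when a requested position falls outside a simulation grid."""


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a full-width at half maximum to the Gaussian standard deviation."""
    return fwhm / _FWHM


@dataclass(frozen=True)
class Medium:
    """Homogeneous acoustic medium.

    Parameters
    ----------
    density:
        Mass density rho in kg/m^3.
    speed_of_sound:
        Longitudinal sound speed c in m/s.

    Defaults are water-like soft tissue (1000 kg/m^3, 1500 m/s).
    """

    density: float = 1000.0
    speed_of_sound: float = 1500.0

    def __post_init__(self) -> None:
        if not (self.density > 0 and np.isfinite(self.density)):
            raise InvalidMediumError(f"density must be > 0, got {self.density}")
        if not (self.speed_of_sound > 0 and np.isfinite(self.speed_of_sound)):
            raise InvalidMediumError(
                f"speed_of_sound must be > 0, got {self.speed_of_sound}"
            )


@dataclass(frozen=True)
class SonicationConfig:
    """Sonication protocol: carrier, pressure, pulse timing and focal geometry.

    All values SI.  The defaults reproduce the stimulation protocol this
    package is built around: 150 ms pulses at 3 MHz, peak pressure up to
    2.8 MPa, 20 stimuli separated by 10 s, a 350 um lateral focal spot and a
    3x larger axial extent (the axial/lateral ratio is an assumption exposed
    here, since only the lateral spot size is measured).
    """

    carrier_frequency: float = 3.0e6  # Hz
    peak_pressure: float = 2.8e6  # Pa
    pulse_duration: float = 0.150  # s
    focus_position: tuple[float, float, float] = (0.0, 0.0, 0.0)  # m
    focal_fwhm_lateral: float = 350e-6  # m
    focal_fwhm_axial: float = 1050e-6  # m
    inter_stimulus_interval: float = 10.0  # s
    n_stimuli: int = 20

    def __post_init__(self) -> None:
        if self.carrier_frequency <= 0:
            raise InvalidFrequencyError(
                f"carrier_frequency must be > 0, got {self.carrier_frequency}"
            )
        if not 0 < self.pulse_duration < self.inter_stimulus_interval:
            raise ValueError(
                "pulse_duration must satisfy 0 < pulse_duration < "
                f"inter_stimulus_interval, got {self.pulse_duration} vs "
                f"{self.inter_stimulus_interval}"
            )
        if self.focal_fwhm_lateral <= 0 or self.focal_fwhm_axial <= 0:
            raise ValueError("focal FWHM values must be > 0")
        if self.n_stimuli < 1:
            raise ValueError(f"n_stimuli must be >= 1, got {self.n_stimuli}")
        if len(self.focus_position) != 3:
            raise ValueError("focus_position must be a 3-vector")

    @property
    def peak_pressure_mpa(self) -> float:
        return self.peak_pressure / 1e6

    @property
    def carrier_frequency_mhz(self) -> float:
        return self.carrier_frequency / 1e6


@dataclass
class IntensityField3D:
    """Time-invariant acoustic intensity map I(x, y, z) on a rectilinear grid.

    Axes are strictly increasing coordinate vectors in metres; values are in
    W/m^2 and non-negative.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    values: np.ndarray  # shape (len(x), len(y), len(z))

    def __post_init__(self) -> None:
        for name, ax in (("x", self.x), ("y", self.y), ("z", self.z)):
            ax = np.asarray(ax, dtype=float)
            if ax.ndim != 1 or len(ax) < 3:
                raise ValueError(f"axis {name} must be 1-D with >= 3 points")
            if not np.all(np.diff(ax) > 0):
                raise ValueError(f"axis {name} must be strictly increasing")
            setattr(self, name, ax)
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (len(self.x), len(self.y), len(self.z))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match axes {expected}"
            )
        if np.any(self.values < 0):
            raise ValueError("intensity values must be non-negative")

    @property
    def steps(self) -> tuple[float, float, float]:
        return (
            float(self.x[1] - self.x[0]),
            float(self.y[1] - self.y[0]),
            float(self.z[1] - self.z[0]),
        )


def pressure_to_intensity(p: float, medium: Medium) -> float:
    """Plane-wave acoustic intensity I = p^2 / (2 rho c) in W/m^2.

    ``p`` is the peak pressure in Pa.  The relation is exactly quadratic in
    pressure, so doubling the pressure quadruples the intensity.
    """
    if p < 0:
        raise ValueError(f"pressure must be >= 0, got {p}")
    return p * p / (2.0 * medium.density * medium.speed_of_sound)


def mechanical_index(p_mpa: float, f_mhz: float) -> float:
    """Mechanical index MI = p / sqrt(f).

    ``p_mpa`` is the peak rarefactional pressure in MPa and ``f_mhz`` the
    carrier frequency in MHz, per the conventional definition.  2.8 MPa at
    3 MHz gives 1.617, i.e. 1.6 to two significant figures, below the 1.9
    regulatory limit for diagnostic ultrasound.
    """
    if f_mhz <= 0:
        raise InvalidFrequencyError(f"frequency must be > 0 MHz, got {f_mhz}")
    if p_mpa < 0:
        raise ValueError(f"pressure must be >= 0, got {p_mpa}")
    return p_mpa / math.sqrt(f_mhz)


def focal_intensity_field(
    config: SonicationConfig,
    medium: Medium,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
) -> IntensityField3D:
    """Gaussian-ellipsoid focal intensity field on the given grid.

    The peak intensity at the focus equals ``pressure_to_intensity`` of the
    configured peak pressure; x and y carry the lateral FWHM and z the axial
    FWHM.  The grid must span the focus, and the lateral grid step must
    resolve the focal spot (step <= FWHM_lateral / 4).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    fx, fy, fz = config.focus_position
    for name, ax, f0 in (("x", x, fx), ("y", y, fy), ("z", z, fz)):
        if not (ax[0] <= f0 <= ax[-1]):
            raise OutOfBoundsError(
                f"focus {name}={f0} outside grid [{ax[0]}, {ax[-1]}]"
            )
    lat_step = max(float(np.max(np.diff(x))), float(np.max(np.diff(y))))
    if lat_step > config.focal_fwhm_lateral / 4.0 + 1e-12:
        raise ValueError(
            f"lateral grid step {lat_step:g} m too coarse; must be <= "
            f"focal_fwhm_lateral/4 = {config.focal_fwhm_lateral / 4.0:g} m"
        )

    peak = pressure_to_intensity(config.peak_pressure, medium)
    s_lat = fwhm_to_sigma(config.focal_fwhm_lateral)
    s_ax = fwhm_to_sigma(config.focal_fwhm_axial)
    gx = np.exp(-0.5 * ((x - fx) / s_lat) ** 2)
    gy = np.exp(-0.5 * ((y - fy) / s_lat) ** 2)
    gz = np.exp(-0.5 * ((z - fz) / s_ax) ** 2)
    values = peak * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    return IntensityField3D(x=x, y=y, z=z, values=values)
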