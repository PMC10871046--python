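"""Finite-difference Pennes bioheat solver.

Solves the temperature rise DT(x, y, z, t) above baseline driven by the
absorbed acoustic power of a sonication pulse:

    d(DT)/dt = alpha * laplacian(DT) - DT / tau + Q / (rho C)

with thermal diffusivity alpha = kappa / (rho C), a blood-perfusion sink of
time constant tau (tau = inf disables perfusion) and a volumetric heat
source Q = 2 * alpha_abs * I active while the pulse is on (the standard
plane-wave absorption source for a linear field).  Boundaries are zero-DT
Dirichlet; the grid is expected to be large enough that the focal heat
never reaches them at an appreciable level.

The time integrator is explicit forward Euler with a 7-point Laplacian.
The internal step is selected automatically at half the explicit stability
bound

    dt <= 1 / (2 alpha (1/hx^2 + 1/hy^2 + 1/hz^2) + 1/tau)

and refined further (tau/50 cap) so that the perfusion decay is resolved to
well under a percent.  A user-forced internal step above the bound raises
``StabilityError`` naming the bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .acoustic import IntensityField3D, OutOfBoundsError

__all__ = [
    "ThermalProperties",
    "TemperatureMovie",
    "StabilityError",
    "DivergenceError",
    "simulate_bioheat",
    "sample_timecourse",
]


class StabilityError(RuntimeError):
    """Raised when a forced time step violates the explicit stability bound."""


class DivergenceError(RuntimeError):
    """Raised when non-finite values appear during time integration."""


@dataclass(frozen=True)
class ThermalProperties:
    """Tissue thermal constants.

    Defaults are desk-scale soft-tissue values (the source publications cite
    literature constants without printing them, so these are labelled as
    package defaults and are config-overridable): conductivity
    0.52 W/(m K), volumetric heat capacity 3.8e6 J/(m^3 K), perfusion time
    constant 300 s, acoustic absorption 5 Np/m at the 3 MHz carrier.
    """

    thermal_conductivity: float = 0.52  # W/(m K)
    volumetric_heat_capacity: float = 3.8e6  # J/(m^3 K)
    perfusion_time_constant: float = 300.0  # s; inf disables perfusion
    acoustic_absorption: float = 5.0  # Np/m

    def __post_init__(self) -> None:
        if self.thermal_conductivity <= 0:
            raise ValueError("thermal_conductivity must be > 0")
        if self.volumetric_heat_capacity <= 0:
            raise ValueError("volumetric_heat_capacity must be > 0")
        if not (self.perfusion_time_constant > 0):
            raise ValueError("perfusion_time_constant must be > 0 (inf allowed)")
        if self.acoustic_absorption <= 0:
            raise ValueError("acoustic_absorption must be > 0")

    @property
    def diffusivity(self) -> float:
        """Thermal diffusivity alpha = kappa / (rho C) in m^2/s."""
        return self.thermal_conductivity / self.volumetric_heat_capacity


@dataclass
class TemperatureMovie:
    """Temperature rise DT(x, y, z, t) on a rectilinear grid.

    ``values`` has shape (n_times, nx, ny, nz) in kelvin above baseline;
    ``times`` is uniform starting at 0 where DT equals the initial
    condition (zero by default).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    times: np.ndarray
    values: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def _stability_bound(alpha: float, steps: tuple[float, float, float], tau: float) -> float:
    hx, hy, hz = steps
    rate = 2.0 * alpha * (1.0 / hx**2 + 1.0 / hy**2 + 1.0 / hz**2)
    if math.isfinite(tau):
        rate += 1.0 / tau
    return 1.0 / rate


def simulate_bioheat(
    field: IntensityField3D,
    props: ThermalProperties,
    pulse_duration: float,
    t_end: float,
    dt: float,
    *,
    internal_dt: float | None = None,
    initial_temperature: np.ndarray | None = None,
) -> TemperatureMovie:
    """Integrate the Pennes equation and return DT sampled every ``dt`` seconds.

    Parameters
    ----------
    field:
        Acoustic intensity map; the heat source is Q = 2 * alpha_abs * I
        while t <= pulse_duration and zero afterwards.
    pulse_duration, t_end, dt:
        Pulse length, total simulated time and *output* sampling step, all
        in seconds.  ``t_end`` must exceed ``pulse_duration``; set
        ``pulse_duration = 0`` (with an initial condition) for source-free
        relaxation runs.
    internal_dt:
        Optional forced integrator step.  Must divide into ``dt`` and
        respect the explicit stability bound.
    initial_temperature:
        Optional DT at t = 0 (same shape as the field); defaults to zero.
    """
    if t_end <= pulse_duration and pulse_duration > 0:
        raise ValueError("t_end must exceed pulse_duration")
    if dt <= 0 or t_end < dt:
        raise ValueError("require 0 < dt <= t_end")

    alpha = props.diffusivity
    tau = props.perfusion_time_constant
    steps = field.steps
    for ax in (field.x, field.y, field.z):
        d = np.diff(ax)
        if not np.allclose(d, d[0], rtol=1e-6):
            raise ValueError("bioheat grid axes must be uniformly spaced")
    bound = _stability_bound(alpha, steps, tau)

    if internal_dt is not None:
        if internal_dt > bound:
            raise StabilityError(
                f"internal_dt={internal_dt:g} s violates the explicit stability "
                f"bound dt <= {bound:g} s for this grid and diffusivity"
            )
        dt_int = internal_dt
    else:
        dt_int = 0.5 * bound
        if math.isfinite(tau):
            dt_int = min(dt_int, tau / 50.0)
        dt_int = min(dt_int, dt)
    n_sub = max(1, int(math.ceil(dt / dt_int - 1e-9)))
    dt_int = dt / n_sub

    n_out = int(round(t_end / dt)) + 1
    times = np.arange(n_out) * dt

    shape = field.values.shape
    T = np.zeros(shape, dtype=np.float64)
    if initial_temperature is not None:
        T[...] = np.asarray(initial_temperature, dtype=np.float64)
    src = (2.0 * props.acoustic_absorption / props.volumetric_heat_capacity) * field.values

    hx2, hy2, hz2 = (s * s for s in steps)
    perf = (1.0 / tau) if math.isfinite(tau) else 0.0

    out = np.empty((n_out,) + shape, dtype=np.float32)
    out[0] = T

    t = 0.0
    for i_out in range(1, n_out):
        for _ in range(n_sub):
            c = T[1:-1, 1:-1, 1:-1]
            lap = (
                (T[2:, 1:-1, 1:-1] - 2.0 * c + T[:-2, 1:-1, 1:-1]) / hx2
                + (T[1:-1, 2:, 1:-1] - 2.0 * c + T[1:-1, :-2, 1:-1]) / hy2
                + (T[1:-1, 1:-1, 2:] - 2.0 * c + T[1:-1, 1:-1, :-2]) / hz2
            )
            dTdt = alpha * lap - perf * c
            # source active while the *start* of the step is inside the pulse
            if t < pulse_duration - 1e-12:
                dTdt = dTdt + src[1:-1, 1:-1, 1:-1]
            T[1:-1, 1:-1, 1:-1] = c + dt_int * dTdt
            t += dt_int
        if not np.all(np.isfinite(T)):
            raise DivergenceError(
                f"non-finite temperature at t={t:g} s (internal dt {dt_int:g} s)"
            )
        out[i_out] = T

    return TemperatureMovie(x=field.x, y=field.y, z=field.z, times=times, values=out)


def sample_timecourse(
    movie: TemperatureMovie,
    point: tuple[float, float, float],
    *,
    method: str = "trilinear",
) -> np.ndarray:
    """Extract DT(t) at a spatial point, trilinear by default.

    ``method="nearest"`` snaps to the closest grid node instead.
    """
    px, py, pz = point
    axes = (movie.x, movie.y, movie.z)
    for name, ax, p in zip("xyz", axes, (px, py, pz)):
        if not (ax[0] <= p <= ax[-1]):
            raise OutOfBoundsError(f"point {name}={p} outside grid [{ax[0]}, {ax[-1]}]")

    idx = []
    frac = []
    for ax, p in zip(axes, (px, py, pz)):
        f = (p - ax[0]) / (ax[1] - ax[0])
        i = min(int(f), len(ax) - 2)
        idx.append(i)
        frac.append(f - i)
    ix, iy, iz = idx
    fx, fy, fz = frac

    if method == "nearest":
        jx = ix + (1 if fx >= 0.5 else 0)
        jy = iy + (1 if fy >= 0.5 else 0)
        jz = iz + (1 if fz >= 0.5 else 0)
        return movie.values[:, jx, jy, jz].astype(np.float64)
    if method != "trilinear":
        raise ValueError(f"unknown interpolation method {method!r}")

    v = movie.values
    c000 = v[:, ix, iy, iz]
    c100 = v[:, ix + 1, iy, iz]
    c010 = v[:, ix, iy + 1, iz]
    c001 = v[:, ix, iy, iz + 1]
    c110 = v[:, ix + 1, iy + 1, iz]
    c101 = v[:, ix + 1, iy, iz + 1]
    c011 = v[:, ix, iy + 1, iz + 1]
    c111 = v[:, ix + 1, iy + 1, iz + 1]
    return (
        c000 * (1 - fx) * (1 - fy) * (1 - fz)
        + c100 * fx * (1 - fy) * (1 - fz)
        + c010 * (1 - fx) * fy * (1 - fz)
        + c001 * (1 - fx) * (1 - fy) * fz
        + c110 * fx * fy * (1 - fz)
        + c101 * fx * (1 - fy) * fz
        + c011 * (1 - fx) * fy * fz
        + c111 * fx * fy * fz
    ).astype(np.float64)
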