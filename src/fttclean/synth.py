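"""Synthetic widefield movies with the statistical structure the method assumes.

A generated recording is composed multiplicatively on top of a baseline
photon count::

    F(t, r, c) = baseline * bleach(t) * (1 + (resting + ftt + response) / 100)
                 + photon noise

where the percent-scale components are

* ``resting`` — bilaterally mirrored spontaneous background an order of
  magnitude larger than the evoked response.  Its mirror-symmetric part is
  a mesoscale (spatially smooth) random field identical across hemispheres;
  the hemispherically *asymmetric* part is pixel-scale, reflecting that
  homotopic correlation is a property of mesoscale dynamics while residual
  asymmetry lives at fine (vascular/pixel) spatial scales.  Both parts are
  temporally low-pass below ``resting_corner_freq``.  The mixing of the two
  parts realises the configured inter-hemispheric correlation.
* ``ftt`` — the fluoro-thermal tag: the forward-model (acoustic + bioheat +
  quench) signature inserted at every stimulus onset, scaled by
  ``ftt_scale``.
* ``response`` — the evoked calcium transient on the stimulated side only:
  a spatial Gaussian (wider than the focal spot) times an alpha-function
  time kernel.  The kernel starts at the *end* of the sonication pulse —
  the thermal tag precedes the activation — and peaks at
  ``response_latency_to_peak`` after stimulus onset.

Ground truth (amplitudes, latency, focus pixel, optional per-component
movies) is returned alongside the movie for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .acoustic import Medium, SonicationConfig, fwhm_to_sigma
from .bioheat import ThermalProperties
from .pipeline import Movie
from .quench import CameraGeometry, QuenchCalibration, simulate_ftt_signature

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_movie",
    "generate_calibration_data",
    "compose_movie",
]


@dataclass
class SynthConfig:
    """Generator settings.

    Spatial defaults are a 128 x 128 grid at 88 um/pixel (2x binning of the
    44 um optical resolution, keeping desk-scale runtimes) at 25 Hz.  The
    resting background defaults to 10x the evoked response amplitude
    (``resting_amplitude=None`` derives it), with inter-hemispheric
    correlation 0.95.  Amplitudes are percent dF/F0; ``noise_sd`` is in
    counts on a ``baseline_counts`` photon baseline.
    """

    frame_rate: float = 25.0  # Hz
    n_rows: int = 128
    n_cols: int = 128
    pixel_pitch_um: float = 88.0
    duration: float = 204.0  # s
    midline_col: int = 64
    first_onset: float = 5.0  # s
    resting_amplitude: Optional[float] = None  # percent RMS; None -> 10 x response
    resting_corner_freq: float = 1.0  # Hz
    ih_correlation: float = 0.95
    resting_spatial_sigma_px: float = 8.0  # mirror-symmetric (mesoscale) part
    asymmetry_spatial_sigma_px: float = 0.0  # asymmetric part; 0 = pixel-scale
    bleach_time_constant: float = 300.0  # s
    baseline_counts: float = 1000.0
    noise_sd: float = 5.0  # counts
    response_amplitude: float = 1.0  # percent, peak
    response_latency_to_peak: float = 0.5  # s from stimulus onset
    response_onset_delay: Optional[float] = None  # s; None -> pulse duration
    response_fwhm_spatial_um: float = 1000.0
    ftt_scale: float = 1.0
    focus_pixel: tuple[int, int] = (64, 96)
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0.0 <= self.ih_correlation <= 1.0:
            raise ValueError("ih_correlation must be in [0, 1]")
        if self.response_latency_to_peak <= 0:
            raise ValueError("response_latency_to_peak must be > 0")
        if not 0 <= self.midline_col < self.n_cols:
            raise ValueError("midline_col outside frame")

    @property
    def resting_amplitude_effective(self) -> float:
        if self.resting_amplitude is not None:
            return self.resting_amplitude
        return 10.0 * self.response_amplitude


@dataclass
class GroundTruth:
    """What the generator injected, for recovery tests.

    ``components`` (optional) holds the percent-scale component movies plus
    the additive noise in counts; their composition reconstructs the
    emitted movie exactly.
    """

    true_response_amplitude: float  # percent
    true_latency: float  # s
    true_ftt_scale: float
    true_focus_pixel: tuple[int, int]
    baseline_counts: float
    bleach: np.ndarray  # (frames,)
    components: dict[str, np.ndarray] | None = None


def compose_movie(
    baseline: float, bleach: np.ndarray, percent: np.ndarray, noise: np.ndarray
) -> np.ndarray:
    """F = baseline * bleach * (1 + percent/100) + noise, in place on ``percent``.

    Shared by the generator and the ground-truth reconstruction so the
    composition is bit-identical.
    """
    out = percent
    out *= np.float32(0.01)
    out += np.float32(1.0)
    out *= bleach[:, None, None]
    out *= np.float32(baseline)
    out += noise
    return out


def _mirror_cols(n_cols: int, midline: int) -> tuple[np.ndarray, np.ndarray]:
    cols = np.arange(n_cols)
    mirror = 2 * midline - cols
    valid = (mirror >= 0) & (mirror < n_cols)
    return mirror, valid


def _band_limited_noise(
    shape: tuple[int, ...], fs: float, corner_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Temporally band-limited (< corner) Gaussian noise along axis 0, float32.

    A causal 2nd-order Butterworth low-pass with a discarded warm-up
    segment; the spectrum, not the phase, is what matters for a noise
    field.
    """
    sos = np.asarray(signal.butter(2, corner_hz / (fs / 2.0), output="sos"), dtype=np.float32)
    warm = int(min(2.0 * fs / corner_hz, 10 * fs))
    white = rng.standard_normal((shape[0] + warm,) + shape[1:], dtype=np.float32)
    out = signal.sosfilt(sos, white, axis=0)
    return np.ascontiguousarray(out[warm:], dtype=np.float32)


def _bilinear_upsample(coarse: np.ndarray, H: int, W: int) -> np.ndarray:
    """Separable bilinear interpolation of (T, hc, wc) onto (T, H, W) via matmuls."""

    def interp_matrix(n_out: int, n_in: int) -> np.ndarray:
        # coarse samples sit at the centres of n_in equal bins spanning n_out px
        pos = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        pos = np.clip(pos, 0.0, n_in - 1.0)
        i0 = np.minimum(pos.astype(int), n_in - 2)
        w1 = pos - i0
        A = np.zeros((n_out, n_in), dtype=np.float32)
        A[np.arange(n_out), i0] = 1.0 - w1
        A[np.arange(n_out), i0 + 1] = w1
        return A

    T, hc, wc = coarse.shape
    Ar = interp_matrix(H, hc)
    Ac = interp_matrix(W, wc)
    tmp = (coarse.reshape(T * hc, wc) @ Ac.T).reshape(T, hc, W)
    tmp = np.swapaxes(tmp, 1, 2).reshape(T * W, hc) @ Ar.T
    return np.ascontiguousarray(np.swapaxes(tmp.reshape(T, W, H), 1, 2))


def _resting_field(cfg: SynthConfig, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Resting-state background, percent units, RMS-normalised per component."""
    H, W = cfg.n_rows, cfg.n_cols
    fs = cfg.frame_rate
    amp = cfg.resting_amplitude_effective
    rho = cfg.ih_correlation
    mirror, valid = _mirror_cols(W, cfg.midline_col)

    # mesoscale mirror-symmetric part: generated on a 4x coarse grid (the
    # field is band-limited at sigma >> 4 px), upsampled, then symmetrised
    stride = 4
    hc, wc = H // stride + 2, W // stride + 2
    coarse = _band_limited_noise((n_frames, hc, wc), fs, cfg.resting_corner_freq, rng)
    coarse = ndimage.gaussian_filter(
        coarse, sigma=(0.0, cfg.resting_spatial_sigma_px / stride, cfg.resting_spatial_sigma_px / stride),
        mode="reflect",
    )
    sym = _bilinear_upsample(coarse, H, W)
    sym[:, :, valid] = 0.5 * (sym[:, :, valid] + sym[:, :, mirror[valid]])
    sym *= np.float32(np.sqrt(rho) * amp / max(sym.std(), 1e-12))

    # fine-scale hemispherically asymmetric part
    asym = _band_limited_noise((n_frames, H, W), fs, cfg.resting_corner_freq, rng)
    if cfg.asymmetry_spatial_sigma_px > 0:
        asym = ndimage.gaussian_filter(
            asym, sigma=(0.0, cfg.asymmetry_spatial_sigma_px, cfg.asymmetry_spatial_sigma_px),
            mode="reflect",
        )
    asym *= np.float32(np.sqrt(1.0 - rho) * amp / max(asym.std(), 1e-12))

    sym += asym
    return sym


def _alpha_kernel(times: np.ndarray, latency: float, onset_delay: float) -> np.ndarray:
    """Unit-peak alpha function starting at ``onset_delay``, peaking at ``latency``."""
    tau = latency - onset_delay
    if tau <= 0:
        raise ValueError("response_latency_to_peak must exceed the onset delay")
    ts = (times - onset_delay) / tau
    return np.where(ts > 0, ts * np.exp(1.0 - ts), 0.0)


def generate_movie(
    cfg: SynthConfig,
    scfg: SonicationConfig,
    props: ThermalProperties,
    cal: QuenchCalibration,
    *,
    medium: Medium | None = None,
    keep_components: bool = False,
) -> tuple[Movie, GroundTruth]:
    """Emit a synthetic recording plus its ground truth.

    All randomness derives from ``cfg.seed``; the same seed yields a
    bit-identical movie.  ``keep_components=True`` stores the percent-scale
    component movies (and the noise) in the ground truth for decomposition
    tests — at full scale this costs ~1.3 GB, so it defaults to off.
    """
    medium = medium or Medium()
    fs = cfg.frame_rate
    n_frames = int(round(cfg.duration * fs))
    H, W = cfg.n_rows, cfg.n_cols
    onsets = cfg.first_onset + scfg.inter_stimulus_interval * np.arange(scfg.n_stimuli)
    if onsets[-1] + scfg.pulse_duration >= cfg.duration:
        raise ValueError(
            f"duration {cfg.duration} s does not cover {scfg.n_stimuli} stimuli "
            f"every {scfg.inter_stimulus_interval} s from t={cfg.first_onset} s"
        )
    rng = np.random.default_rng(cfg.seed)
    times = np.arange(n_frames) / fs

    percent = np.zeros((n_frames, H, W), dtype=np.float32)
    components: dict[str, np.ndarray] | None = {} if keep_components else None

    # resting background
    if cfg.resting_amplitude_effective > 0:
        resting = _resting_field(cfg, n_frames, rng)
        percent += resting
        if components is not None:
            components["resting"] = resting.copy()
        del resting
    elif components is not None:
        components["resting"] = np.zeros_like(percent)

    onset_frames = [int(np.ceil(t * fs - 0.5)) for t in onsets]

    # fluoro-thermal tag from the forward model, inserted at every onset
    if cfg.ftt_scale > 0:
        camera = CameraGeometry(
            n_rows=H, n_cols=W, pixel_pitch=cfg.pixel_pitch_um * 1e-6, focus_pixel=cfg.focus_pixel
        )
        sig = simulate_ftt_signature(scfg, medium, props, cal, camera, dt=1.0 / fs)
        sig_v = cfg.ftt_scale * sig.values  # (n_sig, H, W)
        ftt = np.zeros_like(percent) if components is not None else None
        for k in onset_frames:
            n = min(len(sig_v), n_frames - k)
            percent[k : k + n] += sig_v[:n]
            if ftt is not None:
                ftt[k : k + n] += sig_v[:n]
        if components is not None:
            components["ftt"] = ftt
    elif components is not None:
        components["ftt"] = np.zeros_like(percent)

    # evoked response: alpha kernel x spatial Gaussian on the stimulated side
    if cfg.response_amplitude > 0:
        delay = cfg.response_onset_delay
        if delay is None:
            delay = scfg.pulse_duration
        sigma_px = fwhm_to_sigma(cfg.response_fwhm_spatial_um) / cfg.pixel_pitch_um
        r0, c0 = cfg.focus_pixel
        half = int(np.ceil(3.0 * sigma_px))
        if (c0 - half < cfg.midline_col and c0 > cfg.midline_col) or (
            c0 + half > cfg.midline_col and c0 < cfg.midline_col
        ):
            raise ValueError(
                "response footprint crosses the midline; it must stay within the "
                "stimulated hemisphere"
            )
        rows = slice(max(0, r0 - half), min(H, r0 + half + 1))
        cols = slice(max(0, c0 - half), min(W, c0 + half + 1))
        rr = np.arange(rows.start, rows.stop) - r0
        cc = np.arange(cols.start, cols.stop) - c0
        foot = np.exp(-0.5 * (rr[:, None] ** 2 + cc[None, :] ** 2) / sigma_px**2).astype(np.float32)
        epoch_t = np.arange(int(np.ceil(4.0 * cfg.response_latency_to_peak * fs))) / fs
        kern = (cfg.response_amplitude * _alpha_kernel(epoch_t, cfg.response_latency_to_peak, delay)).astype(np.float32)
        resp = np.zeros_like(percent) if components is not None else None
        for k in onset_frames:
            n = min(len(kern), n_frames - k)
            patch = kern[:n, None, None] * foot[None]
            percent[k : k + n, rows, cols] += patch
            if resp is not None:
                resp[k : k + n, rows, cols] += patch
        if components is not None:
            components["response"] = resp
    elif components is not None:
        components["response"] = np.zeros_like(percent)

    bleach = np.exp(-times / cfg.bleach_time_constant).astype(np.float32)
    noise = rng.standard_normal(percent.shape, dtype=np.float32)
    noise *= np.float32(cfg.noise_sd)
    if components is not None:
        components["noise"] = noise.copy()
    values = compose_movie(cfg.baseline_counts, bleach, percent, noise)
    del percent, noise

    movie = Movie(
        values=values,
        frame_rate=fs,
        pixel_pitch=cfg.pixel_pitch_um * 1e-6,
        stimulus_onsets=onsets,
        midline_col=cfg.midline_col,
        units="raw",
    )
    truth = GroundTruth(
        true_response_amplitude=cfg.response_amplitude,
        true_latency=cfg.response_latency_to_peak,
        true_ftt_scale=cfg.ftt_scale,
        true_focus_pixel=cfg.focus_pixel,
        baseline_counts=cfg.baseline_counts,
        bleach=bleach,
        components=components,
    )
    return movie, truth


def generate_calibration_data(
    true_slope: float,
    true_intercept: float,
    temps,
    noise_sd: float,
    *,
    seed: int = 0,
) -> pd.DataFrame:
    """Bath-calibration fixture: brightness = intercept + slope * T + noise.

    Returns a DataFrame with the calibration CSV columns
    ``temperature_C`` and ``fluorescence_percent``.
    """
    T = np.asarray(temps, dtype=float)
    if len(T) < 2:
        raise ValueError("need >= 2 temperatures")
    rng = np.random.default_rng(seed)
    F = true_intercept + true_slope * T + rng.normal(0.0, noise_sd, size=T.shape)
    return pd.DataFrame({"temperature_C": T, "fluorescence_percent": F})
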