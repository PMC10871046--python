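"""File I/O: TIFF stacks, calibration CSVs, result bundles with manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .bioheat import TemperatureMovie
from .pipeline import CorrectedResult, Movie

__all__ = [
    "UnsupportedFormatError",
    "read_movie_stack",
    "write_movie_stack",
    "read_calibration_csv",
    "write_temperature_movie",
    "write_results",
]


class UnsupportedFormatError(ValueError):
    """Raised for multi-channel / RGB input stacks."""


def read_movie_stack(
    path: str | Path,
    frame_rate: float,
    stimulus_onsets,
    *,
    pixel_pitch_um: float,
    midline_col: int,
) -> Movie:
    """Load a single-channel multi-page TIFF as a ``Movie``.

    Integer data are promoted to float32 exactly; RGB or multi-channel
    stacks are rejected.  Onsets are validated against the recording
    duration by the ``Movie`` constructor.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise UnsupportedFormatError(
            f"expected a single-channel stack, got shape {arr.shape}"
        )
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]) // 4:
        raise UnsupportedFormatError("RGB/RGBA stacks are not supported")
    return Movie(
        values=arr.astype(np.float32),
        frame_rate=frame_rate,
        pixel_pitch=pixel_pitch_um * 1e-6,
        stimulus_onsets=stimulus_onsets,
        midline_col=midline_col,
        units="raw",
    )


def write_movie_stack(path: str | Path, movie: Movie) -> None:
    tifffile.imwrite(str(path), movie.values.astype(np.float32), photometric="minisblack")


def read_calibration_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column calibration table ``temperature_C,fluorescence_percent``."""
    df = pd.read_csv(path)
    required = {"temperature_C", "fluorescence_percent"}
    if not required.issubset(df.columns):
        raise ValueError(f"calibration CSV must have columns {sorted(required)}")
    return df["temperature_C"].to_numpy(float), df["fluorescence_percent"].to_numpy(float)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, files: list[Path]) -> Path:
    manifest = {
        "files": [{"name": f.name, "sha256": _sha256(f), "bytes": f.stat().st_size} for f in files]
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def write_temperature_movie(out_dir: str | Path, movie: TemperatureMovie, points: dict[str, np.ndarray]) -> dict:
    """Write a simulated temperature movie (npz) plus a CSV of point time courses."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    npz = out_dir / "temperature.npz"
    np.savez_compressed(
        npz, x=movie.x, y=movie.y, z=movie.z, times=movie.times, values=movie.values
    )
    df = pd.DataFrame({"time_s": movie.times, **points})
    csv = out_dir / "timecourses.csv"
    df.to_csv(csv, index=False)
    _write_manifest(out_dir, [npz, csv])
    return {"npz": str(npz), "csv": str(csv)}


def write_results(result: CorrectedResult, out_dir: str | Path, *, config_echo: dict | None = None) -> dict:
    """Write the corrected movie (TIFF), traces (CSV), summary (JSON) and manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tif = out_dir / "corrected.tif"
    tifffile.imwrite(str(tif), result.corrected_movie.values.astype(np.float32), photometric="minisblack")

    csv = out_dir / "traces.csv"
    pd.DataFrame(
        {
            "time_s": result.times,
            "raw": result.raw_trace,
            "ih": result.uncorrected_trace,
            "corrected": result.corrected_trace,
        }
    ).to_csv(csv, index=False)

    summary = {
        "peak_amplitude_percent": result.peak_amplitude,
        "peak_latency_s": result.peak_latency,
        "ftt_scale_used": result.ftt_scale_used,
        "focus_pixel": list(result.focus_pixel),
        "control_roi_mean_abs_percent": result.control_roi_mean_abs,
        "stage_log": result.stage_log,
    }
    if config_echo is not None:
        summary["config"] = config_echo
    js = out_dir / "summary.json"
    js.write_text(json.dumps(summary, indent=2, default=float))

    mpath = _write_manifest(out_dir, [tif, csv, js])
    return {"tiff": str(tif), "csv": str(csv), "json": str(js), "manifest": str(mpath)}
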