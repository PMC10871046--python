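"""File I/O, YAML configuration and the command-line interface."""

import hashlib
import json

import numpy as np
import pytest
import tifffile
import yaml
from click.testing import CliRunner

import fttclean as f
from fttclean import io
from fttclean.cli import main
from fttclean.config import ConfigError, config_to_dict, load_config

from conftest import make_movie, make_small_pcfg, make_small_synth


class TestMovieStackIO:
    def test_float32_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        m = make_movie(rng.standard_normal((20, 8, 8)).astype(np.float32), onsets=(0.5,))
        path = tmp_path / "m.tif"
        io.write_movie_stack(path, m)
        back = io.read_movie_stack(path, 25.0, [0.5], pixel_pitch_um=88.0, midline_col=4)
        np.testing.assert_array_equal(back.values, m.values)

    def test_uint16_promoted_exactly(self, tmp_path):
        arr = np.arange(20 * 4 * 4, dtype=np.uint16).reshape(20, 4, 4)
        path = tmp_path / "m16.tif"
        tifffile.imwrite(str(path), arr)
        back = io.read_movie_stack(path, 25.0, [0.2], pixel_pitch_um=88.0, midline_col=2)
        assert back.values.dtype == np.float32
        np.testing.assert_array_equal(back.values, arr.astype(np.float32))

    def test_rgb_rejected(self, tmp_path):
        arr = np.zeros((20, 16, 16, 3), dtype=np.uint8)
        path = tmp_path / "rgb.tif"
        tifffile.imwrite(str(path), arr, photometric="rgb")
        with pytest.raises(io.UnsupportedFormatError):
            io.read_movie_stack(path, 25.0, [0.2], pixel_pitch_um=88.0, midline_col=8)

    def test_onsets_beyond_duration_rejected(self, tmp_path):
        path = tmp_path / "m.tif"
        tifffile.imwrite(str(path), np.zeros((10, 4, 4), dtype=np.float32), photometric="minisblack")
        with pytest.raises(ValueError, match="onsets"):
            io.read_movie_stack(path, 25.0, [5.0], pixel_pitch_um=88.0, midline_col=2)


@pytest.fixture(scope="module")
def small_result(props, cal):
    scfg = f.SonicationConfig(n_stimuli=5, inter_stimulus_interval=4.0)
    cfg = make_small_synth()
    movie, _ = f.generate_movie(cfg, scfg, props, cal)
    return f.run_pipeline(movie, make_small_pcfg(), scfg, props, cal)


class TestWriteResults:
    def test_summary_round_trip_exact(self, small_result, tmp_path):
        paths = io.write_results(small_result, tmp_path)
        s = json.loads(open(paths["json"]).read())
        assert s["peak_amplitude_percent"] == small_result.peak_amplitude
        assert s["peak_latency_s"] == small_result.peak_latency

    def test_csv_row_count_matches_epoch(self, small_result, tmp_path):
        import pandas as pd

        paths = io.write_results(small_result, tmp_path)
        df = pd.read_csv(paths["csv"])
        assert len(df) == len(small_result.times)
        assert list(df.columns) == ["time_s", "raw", "ih", "corrected"]

    def test_manifest_checksums_validate(self, small_result, tmp_path):
        paths = io.write_results(small_result, tmp_path)
        manifest = json.loads(open(paths["manifest"]).read())
        for entry in manifest["files"]:
            digest = hashlib.sha256((tmp_path / entry["name"]).read_bytes()).hexdigest()
            assert digest == entry["sha256"]


def _config_dict(**synth_overrides):
    synth = dict(
        n_rows=32, n_cols=32, midline_col=16, focus_pixel=[16, 24],
        duration=26.0, first_onset=3.0, seed=3, response_fwhm_spatial_um=500.0,
    )
    synth.update(synth_overrides)
    return {
        "sonication": {"n_stimuli": 5, "inter_stimulus_interval": 4.0},
        "medium": {},
        "thermal": {},
        "calibration": {"slope": -2.0, "intercept": 0.0},
        "pipeline": {
            "epoch_pre_s": 1.0, "epoch_post_s": 2.5, "roi_fwhm_um": 500.0,
            "signature_t_end_s": 2.0, "focus_pixel": [16, 24],
        },
        "synth": synth,
    }


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(_config_dict()))
        cfg = load_config(p)
        assert cfg.sonication.n_stimuli == 5
        assert cfg.synth.focus_pixel == (16, 24)
        assert cfg.calibration.slope == -2.0
        echo = config_to_dict(cfg)
        assert echo["synth"]["seed"] == 3

    def test_unknown_key_rejected(self, tmp_path):
        d = _config_dict()
        d["pipeline"]["bogus_knob"] = 1
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(d))
        with pytest.raises(ConfigError, match="bogus_knob"):
            load_config(p)

    def test_missing_path_rejected(self, tmp_path):
        d = _config_dict()
        d["paths"] = {"movie": str(tmp_path / "nope.tif")}
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(d))
        with pytest.raises(ConfigError, match="does not exist"):
            load_config(p)


class TestCli:
    def test_generate_then_run_pipeline(self, tmp_path):
        runner = CliRunner()
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(_config_dict()))
        r1 = runner.invoke(
            main, ["generate-synthetic", "--config", str(cfg_path), "--out", str(tmp_path / "data")]
        )
        assert r1.exit_code == 0, r1.output
        assert (tmp_path / "data" / "movie.tif").exists()
        truth = json.loads((tmp_path / "data" / "truth.json").read_text())
        assert truth["true_latency"] == 0.5

        r2 = runner.invoke(
            main,
            [
                "run-pipeline",
                "--movie", str(tmp_path / "data" / "movie.tif"),
                "--config", str(cfg_path),
                "--out", str(tmp_path / "out"),
            ],
        )
        assert r2.exit_code == 0, r2.output
        assert "peak amplitude" in r2.output
        summary = json.loads((tmp_path / "out" / "summary.json").read_text())
        assert "peak_latency_s" in summary

        r3 = runner.invoke(main, ["report", "--summary", str(tmp_path / "out" / "summary.json")])
        assert r3.exit_code == 0, r3.output
        assert "peak latency" in r3.output

    def test_calibrate_quench(self, tmp_path):
        df = f.generate_calibration_data(-1.1, 104.0, np.linspace(22, 40, 6), 0.0)
        csv = tmp_path / "cal.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "cal.json"
        r = CliRunner().invoke(main, ["calibrate-quench", "--csv", str(csv), "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert "slope: -1.1000" in r.output
        assert json.loads(out.read_text())["slope"] == pytest.approx(-1.1)

    def test_simulate_thermal(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(_config_dict()))
        r = CliRunner().invoke(
            main,
            ["simulate-thermal", "--config", str(cfg_path), "--out", str(tmp_path / "thermal"),
             "--t-end", "0.4", "--dt", "0.05"],
        )
        assert r.exit_code == 0, r.output
        assert "peak temperature rise" in r.output
        import pandas as pd

        df = pd.read_csv(tmp_path / "thermal" / "timecourses.csv")
        assert "dT_K_at_0um" in df.columns
        assert df["dT_K_at_0um"].max() > df["dT_K_at_800um"].max()
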