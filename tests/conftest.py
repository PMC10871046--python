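"""Shared fixtures: desk-scale configurations for fast unit tests."""

import numpy as np
import pytest

import fttclean as f


@pytest.fixture(scope="session")
def medium():
    return f.Medium()


@pytest.fixture(scope="session")
def props():
    return f.ThermalProperties()


@pytest.fixture(scope="session")
def cal():
    return f.QuenchCalibration(slope=-2.0, intercept=0.0)


@pytest.fixture(scope="session")
def small_scfg():
    """Five 150 ms pulses, 4 s apart: short enough for second-scale tests."""
    return f.SonicationConfig(n_stimuli=5, inter_stimulus_interval=4.0)


def make_small_synth(**overrides):
    kw = dict(
        n_rows=32,
        n_cols=32,
        midline_col=16,
        focus_pixel=(16, 24),
        duration=26.0,
        first_onset=3.0,
        seed=3,
        response_fwhm_spatial_um=500.0,
    )
    kw.update(overrides)
    return f.SynthConfig(**kw)


@pytest.fixture
def small_synth():
    return make_small_synth()


def make_small_pcfg(**overrides):
    kw = dict(
        epoch_pre_s=1.0,
        epoch_post_s=2.5,
        roi_fwhm_um=500.0,
        signature_t_end_s=2.0,
        focus_pixel=(16, 24),
    )
    kw.update(overrides)
    return f.PipelineConfig(**kw)


@pytest.fixture
def small_pcfg():
    return make_small_pcfg()


def make_movie(values, fs=25.0, onsets=(1.0,), midline=None, **kw):
    values = np.asarray(values, dtype=np.float32)
    if midline is None:
        midline = values.shape[2] // 2
    return f.Movie(
        values=values,
        frame_rate=fs,
        pixel_pitch=88e-6,
        stimulus_onsets=list(onsets),
        midline_col=midline,
        **kw,
    )
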