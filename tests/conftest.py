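"""Shared fixtures and helpers for the speckleflow test suite."""

import numpy as np
import pytest

from speckleflow.fields import CineLoop, CineMeta
from speckleflow.phantom import (
    FlowModel,
    ImagingConfig,
    ScattererCloud,
    render_frame,
    seed_cloud,
)


def steady(_s):
    """Waveform that is identically 1 (steady flow)."""
    return np.ones_like(np.asarray(_s, dtype=float))


@pytest.fixture
def imaging_small():
    """Small, fast imaging geometry at the acquisition defaults."""
    return ImagingConfig(n_x=64, n_y=64, frames_per_cycle=8, noise_sigma=0.0)


def make_cloud(cfg: ImagingConfig, seed: int = 0) -> ScattererCloud:
    rng = np.random.default_rng(seed)
    model = FlowModel(kind="uniform", peak_speed=1.0)
    return seed_cloud(model, cfg, rng)


def render_shifted_pair(cfg: ImagingConfig, shift_px=(3.0, 0.0), seed: int = 0):
    """Render the same speckle cloud twice, the second time rigidly shifted
    by ``shift_px = (dx, dy)`` pixels.  Noise follows ``cfg.noise_sigma``."""
    cloud = make_cloud(cfg, seed)
    frame_a = render_frame(cloud, cfg, seed=seed + 1)
    shifted = ScattererCloud(
        cloud.positions
        + np.array(shift_px, dtype=float) * cfg.pixel_pitch,
        cloud.reflectivities,
        cloud.bounds,
        cloud.density,
    )
    frame_b = render_frame(shifted, cfg, seed=seed + 2)
    return frame_a, frame_b


def analytic_cine(model: FlowModel, cfg: ImagingConfig) -> CineLoop:
    """CineLoop whose velocity channel holds the analytic flow exactly
    (confidence 1 everywhere); no speckle rendering involved."""
    n = cfg.frames_per_cycle * cfg.n_cycles
    times = np.arange(n) * cfg.dt
    xs = np.arange(cfg.n_x) * cfg.pixel_pitch
    ys = np.arange(cfg.n_y) * cfg.pixel_pitch
    gx, gy = np.meshgrid(xs, ys)
    vel = np.stack(
        [model.evaluate(gx, gy, t, cfg.period) for t in times], axis=0
    )
    shape = (n, cfg.n_y, cfg.n_x)
    meta = CineMeta(cfg.pixel_pitch, cfg.prf, cfg.period, times)
    return CineLoop(np.zeros(shape), vel, np.ones(shape), meta)
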