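"""Pipeline glue: simulate -> track -> quantify -> report.

Each stage reads and writes the HDF5 cine container, so stages can run
individually from the CLI or as one chain via :func:`run_pipeline`.  All
numeric outputs are deterministic for a fixed configuration: artifacts are
stamped with the configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Optional

import numpy as np

from .config import RunConfig
from .errors import QualityError, ValidationError
from .fields import CineLoop, LineProfile
from .hemodynamics import (
    bernoulli_gradient,
    indicators,
    peak_velocity_trace,
    wall_series,
)
from .io import read_cine, write_cine
from .phantom import ImagingConfig, generate_cine
from .tracking import TrackerConfig, track_cine

__all__ = ["run_pipeline", "simulate_stage", "track_stage", "quantify_stage",
           "report_stage", "default_line"]

log = logging.getLogger("speckleflow")


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def default_line(cine: CineLoop, tracker: Optional[TrackerConfig] = None) -> LineProfile:
    """Short-axis sampling line through the image center.

    Runs vertically (anterior -> posterior) at mid length-axis.  Endpoints
    and sample spacing are aligned with the block-matching kernel grid
    (first/last valid kernel rows, one sample per grid stride) so profile
    samples coincide with kernel-center estimates rather than interpolated
    values between them.
    """
    if tracker is None:
        tracker = TrackerConfig()
    _, n_y, n_x = cine.shape
    pitch = cine.meta.pixel_pitch
    imaging = ImagingConfig(
        pixel_pitch=pitch, prf=cine.meta.prf, n_x=n_x, n_y=n_y
    )
    h = tracker.kernel_size // 2
    r = tracker.resolve_radius(imaging)
    centers = np.arange(h, n_y - h, tracker.grid_stride)
    valid = centers[(centers >= h + r) & (centers <= n_y - 1 - h - r)]
    if len(valid) < 4:
        raise ValidationError("image too small for a default profile line")
    x_mid = (n_x - 1) * pitch / 2.0
    n_samples = (valid[-1] - valid[0]) // tracker.grid_stride + 1
    return LineProfile(
        (x_mid, valid[0] * pitch), (x_mid, valid[-1] * pitch),
        n_samples=int(n_samples),
    )


def wall_probe_lines(
    cine: CineLoop,
    tracker: Optional[TrackerConfig] = None,
    spacing_px: int = 8,
) -> list:
    """Parallel short-axis probe lines on kernel-grid columns.

    Replicate copies of :func:`default_line` at several long-axis positions
    (every ``spacing_px`` pixels across the valid kernel hull), for
    ensemble-averaged wall shear series on axially homogeneous flow.
    """
    if tracker is None:
        tracker = TrackerConfig()
    base = default_line(cine, tracker)
    _, n_y, n_x = cine.shape
    pitch = cine.meta.pixel_pitch
    imaging = ImagingConfig(pixel_pitch=pitch, prf=cine.meta.prf, n_x=n_x, n_y=n_y)
    h = tracker.kernel_size // 2
    r = tracker.resolve_radius(imaging)
    centers = np.arange(h, n_x - h, tracker.grid_stride)
    valid = centers[(centers >= h + r) & (centers <= n_x - 1 - h - r)]
    step = max(1, spacing_px // tracker.grid_stride)
    cols = valid[::step]
    return [
        LineProfile(
            (c * pitch, base.p0[1]), (c * pitch, base.p1[1]),
            n_samples=base.n_samples,
        )
        for c in cols
    ]


def _resolve_line(cine: CineLoop, cfg: RunConfig) -> LineProfile:
    if cfg.quantify.line is not None:
        x0, y0, x1, y1 = cfg.quantify.line
        if y1 < y0:  # keep Y increasing toward the posterior wall
            x0, y0, x1, y1 = x1, y1, x0, y0
        return LineProfile((x0, y0), (x1, y1))
    return default_line(cine)


def simulate_stage(cfg: RunConfig, outdir: Path) -> Path:
    seed = cfg.stage_seeds()["simulate"]
    cine, truth = generate_cine(cfg.flow, cfg.imaging, seed)
    path = outdir / "cine.h5"
    write_cine(cine, path, truth=truth)
    log.info(
        "simulate: %d frames of %dx%d px written to %s",
        cine.n_frames, cine.shape[1], cine.shape[2], path,
    )
    return path


def track_stage(cfg: RunConfig, cine_path: Path, outdir: Path) -> Path:
    cine, truth = read_cine(cine_path)
    tracked = track_cine(cine, cfg.tracker)
    path = outdir / "tracked.h5"
    write_cine(tracked, path, truth=truth)
    log.info("track: %d frame pairs tracked, written to %s",
             cine.n_frames - 1, path)
    return path


def quantify_stage(cfg: RunConfig, tracked_path: Path, outdir: Path) -> dict:
    cine, _ = read_cine(tracked_path)
    line = _resolve_line(cine, cfg)
    q = cfg.quantify
    summary = {}
    for wall in ("anterior", "posterior"):
        series = wall_series(
            cine, line, wall, mu=q.mu,
            confidence_threshold=q.confidence_threshold,
        )
        ind = indicators(series)
        summary[f"tawss_{wall}"] = ind.tawss
        summary[f"osi_{wall}"] = ind.osi
        np.savetxt(
            outdir / f"wss_{wall}.csv",
            np.column_stack([series.times, series.wss]),
            delimiter=",", header="time_s,wss_pa", comments="",
        )
    trace = peak_velocity_trace(cine, line)
    trace.to_csv(outdir / "peak_velocity.csv", index=False)
    v_peak = float(trace["v_peak_mps"].max())
    summary["v_peak_mps"] = v_peak
    summary["bernoulli_mmhg"] = bernoulli_gradient(v_peak)
    summary["mean_confidence"] = float(trace["mean_confidence"].mean())
    log.info("quantify: v_peak=%.3f m/s, TAWSS post=%.3f Pa, OSI post=%.3f",
             v_peak, summary["tawss_posterior"], summary["osi_posterior"])
    return summary


def report_stage(cfg: RunConfig, tracked_path: Path, outdir: Path) -> list:
    """Render snapshot/trace/profile panels as PNGs; returns the paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cine, _ = read_cine(tracked_path)
    line = _resolve_line(cine, cfg)
    phases = cine.phases()
    paths = []

    fig, axes = plt.subplots(1, 4, figsize=(16, 4))
    for ax, target in zip(axes, (0.0, 0.2, 0.4, 0.8)):
        kf = int(np.argmin(np.abs(phases - target)))
        speed = np.linalg.norm(cine.velocity[kf], axis=-1)
        im = ax.imshow(speed, origin="upper", cmap="viridis")
        step = max(1, cine.shape[2] // 16)
        yy, xx = np.mgrid[0:cine.shape[1]:step, 0:cine.shape[2]:step]
        ax.quiver(
            xx, yy,
            cine.velocity[kf, ::step, ::step, 0],
            cine.velocity[kf, ::step, ::step, 1],
            color="w", scale=20,
        )
        ax.set_title(f"t/T = {phases[kf]:.2f}")
        fig.colorbar(im, ax=ax, label="|v| (m/s)")
    p = outdir / "flow_snapshots.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)

    trace = peak_velocity_trace(cine, line)
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 5))
    ax1.plot(trace["phase"], trace["v_peak_mps"])
    ax1.set_ylabel("peak |V| (m/s)")
    ax2.plot(trace["phase"], trace["mean_confidence"])
    ax2.set_ylabel("mean confidence")
    ax2.set_xlabel("t/T")
    p = outdir / "traces.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)

    from .fields import extract_profile

    kf = int(np.argmin(np.abs(phases - 0.2)))
    prof = extract_profile(cine, line, kf)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(prof["Y_mm"], prof["v_long"])
    ax.set_xlabel("Y (mm, anterior -> posterior)")
    ax.set_ylabel("V long (m/s)")
    ax.axhline(0.0, color="k", lw=0.5)
    p = outdir / "profile_peak_systole.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)
    log.info("report: wrote %d figures to %s", len(paths), outdir)
    return paths


def run_pipeline(cfg: RunConfig, make_figures: bool = True) -> dict:
    """Execute the full chain; returns (and writes) the summary JSON."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    def _stage(name, fn, *args):
        try:
            return fn(*args)
        except (ValidationError, QualityError) as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    cine_path = _stage("simulate", simulate_stage, cfg, outdir)
    tracked_path = _stage("track", track_stage, cfg, cine_path, outdir)
    summary = _stage("quantify", quantify_stage, cfg, tracked_path, outdir)
    if make_figures:
        _stage("report", report_stage, cfg, tracked_path, outdir)
    summary["config_hash"] = _config_hash(cfg)
    summary["seed"] = cfg.seed
    with open(outdir / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
    return summary
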