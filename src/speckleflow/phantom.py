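"""Synthetic blood-speckle cine phantoms with analytically known flow.

A phantom is built from three pieces:

* a :class:`FlowModel` — an analytic, time-periodic 2D velocity field
  ``v(x, y, t)`` in m/s (long axis ``x``, short axis ``y``; ``y`` grows
  toward the posterior wall);
* a :class:`ScattererCloud` — random point scatterers advected by the flow;
* an imaging model (:class:`ImagingConfig`) that renders the cloud into
  brightness frames by summing Gaussian point-spread functions and adding
  noise.

Because the flow is analytic, every downstream stage (block-matching
velocimetry, shear-stress indicators) can be validated against exact ground
truth — the substitute for in-vivo cine loops, which are not publicly
available for this modality.

Frames are spaced at the pulse repetition interval 1/prf and one cardiac
cycle spans ``frames_per_cycle`` frames, so the phantom's cycle period is
``frames_per_cycle / prf``.  The cycle is therefore compressed in wall-clock
time relative to physiology; the quantities the tracker and the phase axis
t/T see — displacement per frame pair and fraction of the cycle — are kept
in the clinically reported regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Tuple

import numpy as np

from .errors import DomainError, ParameterError, ValidationError

__all__ = [
    "ImagingConfig",
    "FlowModel",
    "ScattererCloud",
    "systolic_waveform",
    "evaluate_flow",
    "seed_cloud",
    "advect",
    "render_frame",
    "generate_cine",
    "preop_like_flow",
    "postop_like_flow",
]


def systolic_waveform(phase):
    """Raised-cosine systolic envelope w(t/T) in [0, 1].

    Rises from 0 at t/T=0 to 1 at peak systole t/T=0.2, falls back to 0 at
    end-systole t/T=0.5 and stays 0 through diastole.  Periodic with the
    cardiac period.
    """
    s = np.atleast_1d(np.asarray(phase, dtype=float)) % 1.0
    w = np.zeros_like(s)
    rise = s < 0.2
    w[rise] = 0.5 * (1.0 - np.cos(np.pi * s[rise] / 0.2))
    fall = (s >= 0.2) & (s < 0.5)
    w[fall] = 0.5 * (1.0 + np.cos(np.pi * (s[fall] - 0.2) / 0.3))
    if np.isscalar(phase) or np.ndim(phase) == 0:
        return float(w[0])
    return w


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition geometry and rendering parameters.

    Defaults follow the clinical acquisition this package models:
    0.0825 mm/pixel pitch and a 6 kHz pulse repetition frequency.
    """

    pixel_pitch: float = 0.0825  # mm / pixel
    prf: float = 6000.0  # Hz; frame rate of the tracked cine
    n_x: int = 128  # pixels along the long (flow) axis
    n_y: int = 128  # pixels along the short axis
    psf_sigma_x: float = 1.2  # Gaussian PSF width, pixels
    psf_sigma_y: float = 1.2
    noise_sigma: float = 0.02  # additive brightness noise (speckle peak ~1)
    noise_ramp: float = 0.0  # fractional noise growth per mm of depth (y)
    frames_per_cycle: int = 50
    n_cycles: int = 1

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValidationError("pixel_pitch must be positive")
        if self.prf <= 0:
            raise ValidationError("prf must be positive")
        if self.psf_sigma_x <= 0 or self.psf_sigma_y <= 0:
            raise ValidationError("PSF sigmas must be positive")
        if self.frames_per_cycle < 4:
            raise ValidationError("frames_per_cycle must be >= 4")
        if self.n_x < 2 or self.n_y < 2:
            raise ValidationError("image must be at least 2x2 pixels")
        if self.n_cycles < 1:
            raise ValidationError("n_cycles must be >= 1")

    @property
    def dt(self) -> float:
        """Frame interval in seconds (= 1/prf)."""
        return 1.0 / self.prf

    @property
    def period(self) -> float:
        """Cardiac period of the phantom cycle in seconds."""
        return self.frames_per_cycle / self.prf

    @property
    def fov_x(self) -> float:
        """Physical long-axis extent, mm (coordinate of the last pixel)."""
        return (self.n_x - 1) * self.pixel_pitch

    @property
    def fov_y(self) -> float:
        return (self.n_y - 1) * self.pixel_pitch


@dataclass(frozen=True)
class FlowModel:
    """Analytic time-varying 2D velocity field.

    ``kind`` selects the spatial structure:

    uniform
        plug flow ``(peak_speed * w(t/T), 0)`` everywhere.
    parabolic
        Poiseuille-like channel profile across ``jet_width`` centred at
        ``jet_center_y``, zero outside.
    tophat_jet
        nearly uniform core with thin tanh shear layers — the symmetric
        post-repair outflow profile.
    stenotic_jet
        a forward jet that narrows and drifts anteriorly (toward low y) as
        systole develops, superposed with a retrograde recirculation lobe on
        the posterior aspect — the pre-repair picture, with a sign change of
        axial velocity across the shear layer.

    All kinds share the periodic systolic envelope ``waveform`` (default
    :func:`systolic_waveform`, peaking at t/T = 0.2).  Velocities are m/s,
    lengths mm.
    """

    kind: str = "uniform"
    peak_speed: float = 1.5  # m/s at peak systole
    jet_center_y: float = 5.3  # mm
    jet_width: float = 4.4  # mm, fully developed (peak-systole) full width
    deflection: float = 1.5  # mm anterior drift of the jet over systole
    recirculation_strength: float = 0.5  # fraction of peak_speed reversed
    waveform: Optional[Callable[[np.ndarray], np.ndarray]] = None
    fov: Optional[Tuple[float, float]] = None  # (fov_x, fov_y) mm, optional

    _KINDS = ("uniform", "parabolic", "tophat_jet", "stenotic_jet")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValidationError(
                f"unknown flow kind {self.kind!r}; expected one of {self._KINDS}"
            )
        if self.peak_speed < 0:
            raise ValidationError("peak_speed must be non-negative")
        if self.jet_width <= 0:
            raise ValidationError("jet_width must be positive")

    def envelope(self, phase):
        w = self.waveform if self.waveform is not None else systolic_waveform
        return w(phase)

    def evaluate(self, x, y, t, period: float, check_domain: bool = True):
        """Ground-truth velocity (m/s) at physical (x, y) mm and time t s.

        Broadcasts over array inputs; returns an array of shape
        ``broadcast(x, y, t).shape + (2,)`` with components (vx, vy).
        """
        if period <= 0:
            raise ParameterError("period must be positive")
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        t = np.asarray(t, dtype=float)
        if check_domain and self.fov is not None:
            fx, fy = self.fov
            if np.any(x < 0) or np.any(x > fx) or np.any(y < 0) or np.any(y > fy):
                raise DomainError("coordinates outside the field of view")
        s = (t / period) % 1.0
        w = np.asarray(self.envelope(s), dtype=float)
        x, y, w = np.broadcast_arrays(x, y, w)
        vx = np.zeros(np.broadcast(x, y, w).shape, dtype=float)

        if self.kind == "uniform":
            vx = self.peak_speed * w
        elif self.kind == "parabolic":
            u = (y - self.jet_center_y) / (self.jet_width / 2.0)
            vx = self.peak_speed * w * np.clip(1.0 - u * u, 0.0, None)
        elif self.kind == "tophat_jet":
            delta = self.jet_width / 12.0
            lo = self.jet_center_y - self.jet_width / 2.0
            hi = self.jet_center_y + self.jet_width / 2.0
            prof = 0.5 * (np.tanh((y - lo) / delta) - np.tanh((y - hi) / delta))
            vx = self.peak_speed * w * prof
        elif self.kind == "stenotic_jet":
            # Two superposed structures drive the pre-repair hemodynamics:
            #
            # * a forward jet core (squared-parabola, C1 edges) that narrows
            #   and deflects anteriorly as systole develops;
            # * a posterior lobe of fixed geometry (parabolic, so its
            #   velocity gradient is linear across the near-wall band and
            #   finite tracking kernels average it without bias) whose
            #   amplitude crossfades from a forward "wash" early in systole
            #   to retrograde recirculation once the jet detaches.
            #
            # The crossfade produces the posterior-wall WSS sign change over
            # the cycle that distinguishes the stenotic regime, without
            # sweeping steep spatial structure through the near-wall band.
            sb = np.broadcast_to(np.asarray(s, dtype=float), vx.shape)
            g_jet = np.clip(sb / 0.35, 0.0, 1.0)
            g_rec = np.clip((sb - 0.1) / 0.15, 0.0, 1.0)
            width = self.jet_width * (1.2 - 0.2 * g_jet)
            center = self.jet_center_y - self.deflection * g_jet
            u = (y - center) / (width / 2.0)
            vx = self.peak_speed * w * np.clip(1.0 - u * u, 0.0, None) ** 2
            # posterior band geometry is anchored to the tract center, not
            # the jet width: apex 2.4 mm posterior of it, half-width 2.4 mm,
            # so the near-wall flank carries a strong, linear-in-y gradient
            apex = self.jet_center_y + 2.4
            wr = 2.4
            ur = (y - apex) / wr
            wash = 0.5 * (1.0 - g_rec)
            fade = wash - self.recirculation_strength * g_rec
            amp = self.peak_speed * w * fade
            vx = vx + amp * np.clip(1.0 - ur * ur, 0.0, None)

        out = np.stack([vx, np.zeros_like(vx)], axis=-1)
        return out


def evaluate_flow(model: FlowModel, x, y, t, period: float):
    """Functional wrapper around :meth:`FlowModel.evaluate`."""
    return model.evaluate(x, y, t, period)


@dataclass
class ScattererCloud:
    """Point scatterers: positions (N, 2) mm as (x, y), per-point amplitude."""

    positions: np.ndarray
    reflectivities: np.ndarray
    bounds: Tuple[float, float, float, float]  # (x0, x1, y0, y1) incl. margin
    density: float  # scatterers per mm^2

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.reflectivities = np.asarray(self.reflectivities, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValidationError("positions must have shape (N, 2)")
        if len(self.reflectivities) != len(self.positions):
            raise ValidationError("positions and reflectivities disagree in length")

    def __len__(self) -> int:
        return len(self.positions)


def _psf_area_mm2(cfg: ImagingConfig) -> float:
    return 2.0 * np.pi * cfg.psf_sigma_x * cfg.psf_sigma_y * cfg.pixel_pitch**2


def default_density(cfg: ImagingConfig, per_psf: float = 4.0) -> float:
    """Scatterer density giving ``per_psf`` scatterers per PSF area.

    Four per resolution cell yields fully developed speckle texture.
    """
    return per_psf / _psf_area_mm2(cfg)


def seed_cloud(
    model: FlowModel,
    cfg: ImagingConfig,
    rng: np.random.Generator,
    density: Optional[float] = None,
) -> ScattererCloud:
    """Uniform random cloud over the field of view plus a motion margin.

    The margin covers the per-frame peak displacement plus the PSF support so
    scatterers entering the frame are already rendered consistently.
    """
    if density is None:
        density = default_density(cfg)
    sigma_px = max(cfg.psf_sigma_x, cfg.psf_sigma_y)
    margin = (
        4.0 * sigma_px * cfg.pixel_pitch
        + 1000.0 * model.peak_speed / cfg.prf
        + cfg.pixel_pitch
    )
    x0, x1 = -margin, cfg.fov_x + margin
    y0, y1 = -margin, cfg.fov_y + margin
    n = int(round(density * (x1 - x0) * (y1 - y0)))
    pos = np.column_stack(
        [rng.uniform(x0, x1, size=n), rng.uniform(y0, y1, size=n)]
    )
    refl = rng.rayleigh(scale=1.0, size=n)
    return ScattererCloud(pos, refl, (x0, x1, y0, y1), density)


def advect(
    cloud: ScattererCloud,
    model: FlowModel,
    t: float,
    dt: float,
    period: float,
    rng: np.random.Generator,
) -> ScattererCloud:
    """Move scatterers through one frame interval with a midpoint (RK2) step.

    Scatterers leaving the margined domain re-enter periodically at the
    opposite edge of the axis they left (the inflow edge for their local flow
    direction) with fresh reflectivities, conserving the scatterer count.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    x = cloud.positions[:, 0]
    y = cloud.positions[:, 1]
    v1 = model.evaluate(x, y, t, period, check_domain=False)
    # m/s -> mm/s is *1000
    xm = x + 1000.0 * v1[..., 0] * dt / 2.0
    ym = y + 1000.0 * v1[..., 1] * dt / 2.0
    v2 = model.evaluate(xm, ym, t + dt / 2.0, period, check_domain=False)
    xn = x + 1000.0 * v2[..., 0] * dt
    yn = y + 1000.0 * v2[..., 1] * dt

    x0, x1, y0, y1 = cloud.bounds
    refl = cloud.reflectivities.copy()
    out_x = (xn < x0) | (xn > x1)
    out_y = (yn < y0) | (yn > y1)
    if np.any(out_x):
        xn = np.where(out_x, x0 + np.mod(xn - x0, x1 - x0), xn)
    if np.any(out_y):
        yn = np.where(out_y, y0 + np.mod(yn - y0, y1 - y0), yn)
    out = out_x | out_y
    if np.any(out):
        refl[out] = rng.rayleigh(scale=1.0, size=int(out.sum()))
    return ScattererCloud(
        np.column_stack([xn, yn]), refl, cloud.bounds, cloud.density
    )


def render_frame(
    cloud: ScattererCloud,
    cfg: ImagingConfig,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render the cloud into an (n_y, n_x) brightness image.

    Each scatterer contributes a separable Gaussian PSF scaled by its
    reflectivity; seeded additive Gaussian noise is applied afterwards
    (optionally growing with depth via ``noise_ramp``).  Deterministic for a
    fixed seed.
    """
    if len(cloud) == 0:
        raise ValidationError("cannot render an empty scatterer cloud")
    if rng is None:
        rng = np.random.default_rng(seed)
    px = cloud.positions[:, 0] / cfg.pixel_pitch  # column coordinate
    py = cloud.positions[:, 1] / cfg.pixel_pitch  # row coordinate
    rx = int(np.ceil(4.0 * cfg.psf_sigma_x))
    ry = int(np.ceil(4.0 * cfg.psf_sigma_y))
    ox = np.arange(-rx, rx + 1)
    oy = np.arange(-ry, ry + 1)
    cols = np.floor(px)[:, None].astype(int) + ox[None, :]  # (N, 2rx+1)
    rows = np.floor(py)[:, None].astype(int) + oy[None, :]  # (N, 2ry+1)
    gx = np.exp(-((cols - px[:, None]) ** 2) / (2.0 * cfg.psf_sigma_x**2))
    gy = np.exp(-((rows - py[:, None]) ** 2) / (2.0 * cfg.psf_sigma_y**2))
    vals = cloud.reflectivities[:, None, None] * gy[:, :, None] * gx[:, None, :]
    rr = np.broadcast_to(rows[:, :, None], vals.shape)
    cc = np.broadcast_to(cols[:, None, :], vals.shape)
    ok = (rr >= 0) & (rr < cfg.n_y) & (cc >= 0) & (cc < cfg.n_x)
    img = np.zeros((cfg.n_y, cfg.n_x), dtype=float)
    np.add.at(img, (rr[ok], cc[ok]), vals[ok])
    if cfg.noise_sigma > 0:
        noise = rng.normal(0.0, cfg.noise_sigma, size=img.shape)
        if cfg.noise_ramp > 0:
            depth_mm = np.arange(cfg.n_y)[:, None] * cfg.pixel_pitch
            noise = noise * (1.0 + cfg.noise_ramp * depth_mm)
        img = img + noise
    return img


def generate_cine(model: FlowModel, cfg: ImagingConfig, seed: int):
    """Simulate a speckle cine loop plus its ground-truth velocity stack.

    Returns ``(cine, truth)`` where ``cine`` is a
    :class:`speckleflow.fields.CineLoop` whose tissue channel holds the
    rendered speckle frames (velocity zeroed, confidence set to 1 awaiting
    tracking) and ``truth`` is a ``(T_f, n_y, n_x, 2)`` array of the analytic
    flow sampled on the pixel grid at each frame time.
    """
    from .fields import CineLoop, CineMeta  # local import avoids a cycle

    ss = np.random.SeedSequence(seed)
    rng_cloud, rng_noise, rng_reseed = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    model = replace(model, fov=(cfg.fov_x, cfg.fov_y))
    cloud = seed_cloud(model, cfg, rng_cloud)
    n_frames = cfg.frames_per_cycle * cfg.n_cycles
    times = np.arange(n_frames) * cfg.dt
    period = cfg.period

    xs = np.arange(cfg.n_x) * cfg.pixel_pitch
    ys = np.arange(cfg.n_y) * cfg.pixel_pitch
    gx, gy = np.meshgrid(xs, ys)  # (n_y, n_x)

    tissue = np.empty((n_frames, cfg.n_y, cfg.n_x), dtype=float)
    truth = np.empty((n_frames, cfg.n_y, cfg.n_x, 2), dtype=float)
    for k in range(n_frames):
        tissue[k] = render_frame(cloud, cfg, rng=rng_noise)
        truth[k] = model.evaluate(gx, gy, times[k], period)
        if k < n_frames - 1:
            cloud = advect(cloud, model, times[k], cfg.dt, period, rng_reseed)

    meta = CineMeta(
        pixel_pitch=cfg.pixel_pitch,
        prf=cfg.prf,
        period=period,
        frame_times=times,
    )
    cine = CineLoop(
        tissue=tissue,
        velocity=np.zeros_like(truth),
        confidence=np.ones_like(tissue),
        meta=meta,
    )
    return cine, truth


def preop_like_flow(peak_speed: float = 1.5) -> FlowModel:
    """Anteriorly deflected stenotic jet with posterior recirculation."""
    return FlowModel(
        kind="stenotic_jet",
        peak_speed=peak_speed,
        jet_center_y=5.3,
        jet_width=5.2,
        deflection=1.5,
        recirculation_strength=0.5,
    )


def postop_like_flow(peak_speed: float = 1.0) -> FlowModel:
    """Symmetric top-hat outflow jet, no recirculation."""
    return FlowModel(
        kind="tophat_jet",
        peak_speed=peak_speed,
        jet_center_y=5.3,
        jet_width=7.0,
        deflection=0.0,
        recirculation_strength=0.0,
    )
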