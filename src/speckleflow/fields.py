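"""Multichannel cine data model and geometric utilities.

The central container is :class:`CineLoop`: a time-ordered stack of a tissue
(brightness) channel, a two-component in-plane velocity channel (m/s), a
confidence channel in [0, 1], and acquisition metadata.  Physical
coordinates follow the pixel grid: ``x = column * pixel_pitch``,
``y = row * pixel_pitch`` in mm, 0-based, origin at the top-left (anterior)
corner; y grows toward the posterior wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .errors import DomainError, ParameterError, ValidationError

__all__ = [
    "CineMeta",
    "CineLoop",
    "LineProfile",
    "map_to_grid",
    "extract_profile",
    "cycle_phase",
]


@dataclass
class CineMeta:
    """Acquisition metadata: pixel pitch (mm/px), PRF (Hz), period (s),
    per-frame acquisition times (s)."""

    pixel_pitch: float
    prf: float
    period: float
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if not np.isfinite(self.pixel_pitch) or self.pixel_pitch <= 0:
            raise ValidationError("pixel_pitch must be finite and positive")
        if not np.isfinite(self.prf) or self.prf <= 0:
            raise ValidationError("prf must be finite and positive")
        if not np.isfinite(self.period) or self.period <= 0:
            raise ValidationError("period must be finite and positive")
        if self.frame_times.ndim != 1 or np.any(np.diff(self.frame_times) <= 0):
            raise ValidationError("frame_times must be strictly increasing")


@dataclass
class CineLoop:
    """Validated multichannel cine loop.

    Shapes: tissue and confidence are ``(T_f, n_y, n_x)``, velocity is
    ``(T_f, n_y, n_x, 2)`` with components ``(vx long-axis, vy short-axis)``
    in m/s.
    """

    tissue: np.ndarray
    velocity: np.ndarray
    confidence: np.ndarray
    meta: CineMeta

    def __post_init__(self) -> None:
        self.tissue = np.asarray(self.tissue, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.tissue.ndim != 3:
            raise ValidationError("tissue must be (T_f, n_y, n_x)")
        shape = self.tissue.shape
        if self.velocity.shape != shape + (2,):
            raise ValidationError(
                f"velocity shape {self.velocity.shape} does not match "
                f"tissue {shape} + (2,)"
            )
        if self.confidence.shape != shape:
            raise ValidationError(
                f"confidence shape {self.confidence.shape} does not match "
                f"tissue {shape}"
            )
        if not np.all(np.isfinite(self.confidence)):
            raise ValidationError("confidence contains non-finite values")
        if self.confidence.size and (
            self.confidence.min() < 0.0 or self.confidence.max() > 1.0
        ):
            raise ValidationError("confidence must lie in [0, 1]")
        if len(self.meta.frame_times) != shape[0]:
            raise ValidationError("frame_times length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.tissue.shape[0]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.tissue.shape

    def grid(self):
        """Physical coordinate axes (x_mm, y_mm) of the pixel grid."""
        _, n_y, n_x = self.tissue.shape
        return (
            np.arange(n_x) * self.meta.pixel_pitch,
            np.arange(n_y) * self.meta.pixel_pitch,
        )

    def phases(self) -> np.ndarray:
        """t/T in [0, 1) for every frame."""
        return cycle_phase(self.meta.frame_times, self.meta.period)


@dataclass
class LineProfile:
    """A straight sampling line between two physical points (mm).

    The arclength coordinate Y runs from ``p0`` to ``p1``; by convention the
    anterior endpoint (smaller y) should be ``p0`` so Y increases toward the
    posterior wall.  ``n_samples=None`` resolves at sampling time to about
    one sample per pixel pitch.
    """

    p0: Tuple[float, float]
    p1: Tuple[float, float]
    n_samples: Optional[int] = None

    def length(self) -> float:
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))

    def resolve_samples(self, pixel_pitch: float) -> int:
        if self.n_samples is not None:
            if self.n_samples < 2:
                raise ParameterError("n_samples must be >= 2")
            return self.n_samples
        return int(np.ceil(self.length() / pixel_pitch)) + 1

    def sample_points(self, pixel_pitch: float):
        """(x_mm, y_mm, Y_mm) arrays of evenly spaced sample points."""
        n = self.resolve_samples(pixel_pitch)
        frac = np.linspace(0.0, 1.0, n)
        x = self.p0[0] + frac * (self.p1[0] - self.p0[0])
        y = self.p0[1] + frac * (self.p1[1] - self.p0[1])
        return x, y, frac * self.length()


def map_to_grid(tissue, velocity, confidence, meta) -> CineLoop:
    """Assemble and validate a CineLoop from raw channels.

    ``meta`` may be a :class:`CineMeta` or a mapping with keys
    ``pixel_pitch``, ``prf``, ``period``, ``frame_times``.  Physical
    coordinates are implied by the pixel grid (see module docstring).
    """
    if not isinstance(meta, CineMeta):
        try:
            meta = CineMeta(**dict(meta))
        except TypeError as exc:
            raise ValidationError(f"bad metadata: {exc}") from exc
    return CineLoop(
        tissue=np.asarray(tissue, dtype=float),
        velocity=np.asarray(velocity, dtype=float),
        confidence=np.asarray(confidence, dtype=float),
        meta=meta,
    )


def _interp_channel(channel: np.ndarray, x_px, y_px) -> np.ndarray:
    # bilinear; coordinates validated by the caller to lie inside the image
    return map_coordinates(channel, np.vstack([y_px, x_px]), order=1, mode="nearest")


def extract_profile(cine: CineLoop, line: LineProfile, frame: int) -> pd.DataFrame:
    """Bilinearly sample velocity and confidence along a line in one frame.

    Returns a DataFrame with columns ``Y_mm`` (arclength from p0),
    ``v_long``, ``v_short`` (m/s) and ``confidence``.
    """
    if not (0 <= frame < cine.n_frames):
        raise ParameterError(f"frame {frame} out of range")
    _, n_y, n_x = cine.shape
    pitch = cine.meta.pixel_pitch
    x_mm, y_mm, arclen = line.sample_points(pitch)
    x_px = x_mm / pitch
    y_px = y_mm / pitch
    if (
        x_px.min() < 0
        or x_px.max() > n_x - 1
        or y_px.min() < 0
        or y_px.max() > n_y - 1
    ):
        raise DomainError("profile line exits the field of view")
    v_long = _interp_channel(cine.velocity[frame, :, :, 0], x_px, y_px)
    v_short = _interp_channel(cine.velocity[frame, :, :, 1], x_px, y_px)
    conf = _interp_channel(cine.confidence[frame], x_px, y_px)
    return pd.DataFrame(
        {"Y_mm": arclen, "v_long": v_long, "v_short": v_short, "confidence": conf}
    )


def cycle_phase(times, period: float) -> np.ndarray:
    """Normalize times to cardiac phase t/T in [0, 1)."""
    if period <= 0:
        raise ParameterError("period must be positive")
    t = np.asarray(times, dtype=float)
    return np.mod(t, period) / period
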