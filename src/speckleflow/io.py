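"""HDF5 cine container IO.

Layout (all required unless noted):

* datasets ``/tissue`` (T_f, n_y, n_x), ``/velocity`` (T_f, n_y, n_x, 2),
  ``/confidence`` (T_f, n_y, n_x), stored float32;
* optional dataset ``/truth_velocity`` for phantom ground truth;
* root attributes ``pixel_pitch_mm``, ``prf_hz``, ``period_s``,
  ``frame_times_s``.

Round trips are lossless: channels are written float32 and compared at
float32 precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import h5py
import numpy as np

from .errors import ValidationError
from .fields import CineLoop, CineMeta, map_to_grid

__all__ = ["write_cine", "read_cine", "write_tissue_tiff"]

_CHANNELS = ("tissue", "velocity", "confidence")
_ATTRS = ("pixel_pitch_mm", "prf_hz", "period_s", "frame_times_s")


def write_cine(
    cine: CineLoop, path, truth: Optional[np.ndarray] = None
) -> None:
    """Write a CineLoop (and optional ground-truth stack) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("tissue", data=cine.tissue.astype(np.float32))
        f.create_dataset("velocity", data=cine.velocity.astype(np.float32))
        f.create_dataset("confidence", data=cine.confidence.astype(np.float32))
        if truth is not None:
            f.create_dataset("truth_velocity", data=np.asarray(truth, np.float32))
        f.attrs["pixel_pitch_mm"] = cine.meta.pixel_pitch
        f.attrs["prf_hz"] = cine.meta.prf
        f.attrs["period_s"] = cine.meta.period
        f.attrs["frame_times_s"] = cine.meta.frame_times


def write_tissue_tiff(cine: CineLoop, path) -> None:
    """Dump the tissue channel as a multi-page TIFF for visual inspection."""
    import tifffile

    tifffile.imwrite(Path(path), cine.tissue.astype(np.float32))


def read_cine(path, period: Optional[float] = None) -> Tuple[CineLoop, Optional[np.ndarray]]:
    """Read and validate a cine container.

    Returns ``(cine, truth)`` where ``truth`` is the optional ground-truth
    velocity stack or None.  ``period`` overrides a missing ``period_s``
    attribute in legacy files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for name in _CHANNELS:
            if name not in f:
                raise ValidationError(
                    f"cine container {path} is missing the '{name}' dataset"
                )
        for name in ("pixel_pitch_mm", "prf_hz", "frame_times_s"):
            if name not in f.attrs:
                raise ValidationError(
                    f"cine container {path} is missing the '{name}' attribute"
                )
        if "period_s" in f.attrs:
            period_s = float(f.attrs["period_s"])
        elif period is not None:
            period_s = float(period)
        else:
            raise ValidationError(
                f"cine container {path} has no 'period_s' attribute; "
                "supply the cardiac period explicitly (--period)"
            )
        meta = CineMeta(
            pixel_pitch=float(f.attrs["pixel_pitch_mm"]),
            prf=float(f.attrs["prf_hz"]),
            period=period_s,
            frame_times=np.asarray(f.attrs["frame_times_s"], dtype=float),
        )
        try:
            cine = map_to_grid(f["tissue"][()], f["velocity"][()], f["confidence"][()], meta)
        except ValidationError as exc:
            raise ValidationError(f"invalid cine container {path}: {exc}") from exc
        truth = f["truth_velocity"][()].astype(float) if "truth_velocity" in f else None
    return cine, truth
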