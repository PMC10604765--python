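"""Run configuration: one YAML/JSON-serializable object driving the whole
simulate -> track -> quantify -> report chain.

A single global seed is split into per-stage child seeds with
``numpy.random.SeedSequence(seed).spawn``, so each stage is reproducible in
isolation and seeds never collide.  Unknown configuration keys are rejected
rather than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml

from .errors import ValidationError
from .phantom import FlowModel, ImagingConfig, preop_like_flow
from .tracking import TrackerConfig

__all__ = ["QuantifyConfig", "RunConfig"]


@dataclass(frozen=True)
class QuantifyConfig:
    """Options for the hemodynamic quantification stage."""

    line: Optional[Tuple[float, float, float, float]] = None  # x0,y0,x1,y1 mm
    mu: float = 0.0035  # Pa*s
    confidence_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValidationError("mu must be positive")
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValidationError("confidence_threshold must be in [0, 1]")
        if self.line is not None and len(self.line) != 4:
            raise ValidationError("line must be (x0, y0, x1, y1)")


def _build(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls) if f.init}
    unknown = set(data) - names
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in config section '{section}'"
        )
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration."""

    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    flow: FlowModel = field(default_factory=preop_like_flow)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    seed: int = 0
    outdir: str = "speckleflow_run"
    log_level: str = "INFO"

    _SECTIONS = {
        "imaging": ImagingConfig,
        "flow": FlowModel,
        "tracker": TrackerConfig,
        "quantify": QuantifyConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            section = data.pop(name, {})
            if not isinstance(section, dict):
                raise ValidationError(f"config section '{name}' must be a mapping")
            if name == "quantify" and isinstance(section.get("line"), list):
                section = {**section, "line": tuple(section["line"])}
            kwargs[name] = _build(section_cls, section, name)
        for scalar in ("seed", "outdir", "log_level"):
            if scalar in data:
                kwargs[scalar] = data.pop(scalar)
        if data:
            raise ValidationError(f"unknown top-level config key(s) {sorted(data)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {}
        for name in self._SECTIONS:
            section = dataclasses.asdict(getattr(self, name))
            # callables / derived fields are not serialized
            section.pop("waveform", None)
            section.pop("fov", None)
            if name == "quantify" and section.get("line") is not None:
                section["line"] = list(section["line"])
            out[name] = section
        out.update(seed=self.seed, outdir=self.outdir, log_level=self.log_level)
        return out

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        if not isinstance(data, dict):
            raise ValidationError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def stage_seeds(self) -> dict:
        """Deterministic per-stage child seeds below 2**31."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("simulate", "track", "quantify", "report")
        return {
            name: int(child.generate_state(1, np.uint32)[0] % (2**31))
            for name, child in zip(names, children)
        }
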