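"""Per-cell-line parameter presets: load, validate, save, hash.

A preset bundles the detection, segmentation and tracking parameters plus
the frame interval.  Config files are YAML (or JSON, a YAML subset) with
four sections — ``detection``, ``segmentation``, ``tracking`` and the
top-level ``frame_interval_min``/``name`` keys.  Unknown keys are rejected
by name, and omitted keys fall back to the documented defaults, so a
minimal config only states what differs from them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hough import DetectionParams
from .levelset import SegmentationParams
from .tracking import TrackingParams

__all__ = ["PresetConfig", "ConfigError", "load_config", "save_config", "builtin_preset"]


class ConfigError(ValueError):
    pass


@dataclass
class PresetConfig:
    """Named bundle of all pipeline parameters for one cell line / dataset."""

    name: str = "synthetic-default"
    frame_interval_min: float = 5.0
    detection: DetectionParams = field(default_factory=DetectionParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "frame_interval_min": self.frame_interval_min,
            "detection": dataclasses.asdict(self.detection),
            "segmentation": dataclasses.asdict(self.segmentation),
            "tracking": dataclasses.asdict(self.tracking),
        }

    @property
    def hash(self) -> str:
        """Stable short digest of the full parameter set, for output headers."""
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def validate(self) -> "PresetConfig":
        if self.frame_interval_min <= 0:
            raise ConfigError("frame_interval_min must be positive")
        try:
            # DetectionParams validates in __post_init__; re-trigger it
            DetectionParams(**dataclasses.asdict(self.detection))
            self.segmentation.validate()
            self.tracking.validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        return self


def _build_section(cls, section: dict, section_name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {section_name}: {sorted(unknown)}")
    try:
        return cls(**section)
    except ValueError as exc:
        raise ConfigError(f"{section_name}: {exc}") from exc


def preset_from_dict(data: dict) -> PresetConfig:
    known_top = {"name", "frame_interval_min", "detection", "segmentation", "tracking"}
    unknown = set(data) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    cfg = PresetConfig(
        name=data.get("name", "unnamed"),
        frame_interval_min=float(data.get("frame_interval_min", 5.0)),
        detection=_build_section(DetectionParams, data.get("detection", {}) or {}, "detection"),
        segmentation=_build_section(SegmentationParams, data.get("segmentation", {}) or {}, "segmentation"),
        tracking=_build_section(TrackingParams, data.get("tracking", {}) or {}, "tracking"),
    )
    return cfg.validate()


def load_config(path) -> PresetConfig:
    """Parse and validate a YAML/JSON preset file."""
    p = Path(path)
    with open(p) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"config {p} must be a mapping")
    return preset_from_dict(data)


def save_config(path, cfg: PresetConfig) -> None:
    with open(Path(path), "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def builtin_preset(name: str = "synthetic-default") -> PresetConfig:
    """Presets shipped with the package.

    ``synthetic-default`` matches the bundled phase-contrast simulator
    (mitotic radii around 10 px, 5 minutes per frame).
    """
    if name == "synthetic-default":
        return PresetConfig(
            name=name,
            frame_interval_min=5.0,
            detection=DetectionParams(radius_min=7.0, radius_max=13.0,
                                      max_candidates_per_frame=4),
            # eps_grad is raised from the generic default so the
            # normal-velocity image is not dominated by noise ratios in
            # static background; mu is kept small so division necks pinch
            segmentation=SegmentationParams(mu=0.05, omega=2e-3, eps_grad=0.05),
            tracking=TrackingParams(),
        ).validate()
    raise ConfigError(f"unknown preset {name!r}")
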