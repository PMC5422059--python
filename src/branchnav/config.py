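"""Run configuration: one file governs every stage constant.

Detector windows and thresholds, the displacement calibration factor, the
site declination, the projection zone, the sharpness thresholds and the
video parameters are all operator- or site-specific, so none of them is
hard-coded in stage code — stages take their constants from an
:class:`AppConfig`, serializable to/from a single JSON or YAML file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

from branchnav.georef import DEFAULT_DECLINATION, ProjectionSpec
from branchnav.ins_nav import DEFAULT_CALIBRATION_FACTOR
from branchnav.motion_detect import DetectionConfig
from branchnav.sharpness import SharpnessThresholds

__all__ = ["AppConfig"]


@dataclass
class AppConfig:
    """Aggregate configuration for both operating modes."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    calibration_factor: float = DEFAULT_CALIBRATION_FACTOR
    declination: float = DEFAULT_DECLINATION
    projection: ProjectionSpec = field(default_factory=ProjectionSpec)
    thresholds: SharpnessThresholds = field(default_factory=SharpnessThresholds)
    operator: str = "laplacian"
    fps: float = 30.0
    t0_offset: float = 0.0
    retention: float = 0.2
    max_gps_error: float = 5.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "detection": dataclasses.asdict(self.detection),
            "calibration_factor": self.calibration_factor,
            "declination": self.declination,
            "projection": dataclasses.asdict(self.projection),
            "thresholds": dataclasses.asdict(self.thresholds),
            "operator": self.operator,
            "fps": self.fps,
            "t0_offset": self.t0_offset,
            "retention": self.retention,
            "max_gps_error": self.max_gps_error,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AppConfig":
        kwargs = dict(d)
        if "detection" in kwargs:
            kwargs["detection"] = DetectionConfig(**kwargs["detection"])
        if "projection" in kwargs:
            kwargs["projection"] = ProjectionSpec(**kwargs["projection"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = SharpnessThresholds(**kwargs["thresholds"])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str) -> "AppConfig":
        with open(path) as fh:
            text = fh.read()
        if path.endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path: str) -> None:
        d = self.to_dict()
        with open(path, "w") as fh:
            if path.endswith((".yaml", ".yml")):
                import yaml

                yaml.safe_dump(d, fh, sort_keys=False)
            else:
                json.dump(d, fh, indent=2)

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
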