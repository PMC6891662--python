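"""Assay configuration: thresholds, calibration, and run parameters.

The config round-trips losslessly through YAML so a run can be reproduced
from its manifest alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class AssayConfig:
    pixel_size: float = 1.0  # um per pixel
    intensity_threshold: "float | None" = None  # None = automatic (Otsu)
    circularity_threshold: float = 0.6  # c0: spread if circularity < c0
    defect_threshold: int = 3  # d0: spread if convexity defects >= d0
    spot_min_distance: int = 3  # px between detected bacteria spots
    spot_threshold: "float | None" = None  # None = midpoint of channel range
    temperature: float = 298.15  # K, for binding energy <-> Ki
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive (um/px)")
        if not (0.0 < self.circularity_threshold <= 1.1):
            raise ConfigError("circularity_threshold must be in (0, 1.1]")
        if self.defect_threshold < 0:
            raise ConfigError("defect_threshold must be >= 0")
        if self.spot_min_distance < 1:
            raise ConfigError("spot_min_distance must be >= 1")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive (kelvin)")
        if self.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError(f"unknown log level {self.log_level!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AssayConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
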