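"""Pipeline configuration: one dataclass tree, YAML round-trippable.

Defaults mirror the validated parameter set: 250 HU initial threshold,
26-connectivity, 20/10 px box expansion at ends/shafts, 0–30 px training
jitter, 150 HU reference-backend threshold, 10 smoothing iterations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import DataError
from .recognition import RecognitionConfig


@dataclass
class BoxConfig:
    d_end: int = 20
    d_shaft: int = 10
    end_fraction: float = 0.2
    jitter_max: int = 30


@dataclass
class BackendConfig:
    hu_low: float = 150.0
    closing_radius: int = 2
    min_area: int = 5


@dataclass
class RefineConfig:
    fill_3d: bool = False
    resolve_overlaps: bool = True


@dataclass
class ReconstructionConfig:
    smooth_iters: int = 10


@dataclass
class PipelineConfig:
    recognition: RecognitionConfig = field(default_factory=RecognitionConfig)
    boxes: BoxConfig = field(default_factory=BoxConfig)
    backend: BackendConfig = field(default_factory=BackendConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        sections = {
            "recognition": RecognitionConfig,
            "boxes": BoxConfig,
            "backend": BackendConfig,
            "refine": RefineConfig,
            "reconstruction": ReconstructionConfig,
        }
        for key, value in raw.items():
            if key in sections:
                known = {f.name for f in dataclasses.fields(sections[key])}
                unknown = set(value) - known
                if unknown:
                    raise DataError(f"unknown {key} config keys: {sorted(unknown)}")
                kwargs[key] = sections[key](**value)
            elif key == "seed":
                kwargs["seed"] = int(value)
            else:
                raise DataError(f"unknown config section: {key}")
        return cls(**kwargs)
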