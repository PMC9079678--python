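"""Run configuration for the full pipeline.

A :class:`RunConfig` declares the inputs (topology + trajectories, or a
synthetic planted spec), the source/sink node selections, the analysis
thresholds, and the seed.  Configs round-trip through YAML identically,
and every report is stamped with the config hash so results can be tied
back to the exact settings that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class Thresholds:
    """All geometric and reporting thresholds in one place (Angstrom,
    degrees, fractions)."""

    contact_cutoff: float = 4.5       # heavy-atom contact distance
    occupancy: float = 0.75           # contact persistence for an edge
    hydrophobic: float = 6.5          # side-chain center distance
    electrostatic: float = 11.0       # charged side-chain center distance
    hbond_distance: float = 3.5       # donor-acceptor distance
    hbond_angle: float = 120.0        # donor-hydrogen-acceptor angle
    population: float = 0.4           # "strong interaction" report cutoff
    degree_report: int = 10           # hub-degree cutoff in summaries

    def validate(self) -> None:
        numeric = [
            self.contact_cutoff, self.occupancy, self.hydrophobic,
            self.electrostatic, self.hbond_distance, self.hbond_angle,
            self.population, float(self.degree_report),
        ]
        if any(x <= 0 for x in numeric):
            raise ValueError("all thresholds must be positive")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy threshold must be in (0, 1]")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    label: str = "system"
    # file inputs (ignored when synthetic is set)
    topology: str | None = None
    trajectories: list[str] = field(default_factory=list)
    # synthetic input: kwargs for synth.PlantedSpec
    synthetic: dict | None = None
    # node selections (labels like "LIG", "Y403"; sink may list several)
    sources: list[str] = field(default_factory=list)
    sinks: list[str] = field(default_factory=list)
    weaken: list[str] = field(default_factory=list)
    # frame handling
    stride: int = 1
    window: "list[int] | float | None" = None
    superpose: bool | str = "auto"    # auto: skip for synthetic input
    consensus: str = "majority"       # replicate edge voting rule
    interactions: bool = False
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)
        self.validate()

    def validate(self) -> None:
        self.thresholds.validate()
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.synthetic is None and not self.trajectories:
            raise ValueError("config needs trajectories or a synthetic spec")
        if self.synthetic is not None and not isinstance(self.synthetic, dict):
            raise ValueError("synthetic must be a mapping of PlantedSpec fields")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: "str | Path | None" = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "window" in data and isinstance(data["window"], (list, tuple)):
            data["window"] = list(data["window"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, source: "str | Path") -> "RunConfig":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config YAML must be a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable short hash of the canonical config serialization."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
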