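"""Run configuration shared by the detection pipeline and the CLI."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

AGGREGATIONS = ("min", "product", "mean")
VERBOSITY_LEVELS = ("quiet", "info", "debug")


class ConfigError(ValueError):
    """Raised for out-of-range values or unknown configuration keys."""


@dataclass
class RunConfig:
    """Tunable constants of the shift-detection pipeline.

    path_threshold
        Minimum likelihood a complete chain path must have to be kept
        during enumeration.  Together with ``max_path_length`` it bounds
        the search in chains with loops.
    max_path_length
        Hard cap on enumerated path length (number of actions).
    include_initial_prob
        If true, the likelihood of an observed episode is additionally
        multiplied by the initial probability of its first action.  By
        default the initial probability only gates (must be positive).
    criticality_aggregation
        How per-modification criticality values are combined over a
        modification set: ``min`` (most critical member dominates),
        ``product`` or ``mean``.
    anomaly_threshold
        A behavior is flagged anomalous when its risk factor exceeds
        this value.
    seed
        Seed for every stochastic component reachable from this config.
    """

    path_threshold: float = 0.01
    max_path_length: int = 100
    include_initial_prob: bool = False
    criticality_aggregation: str = "min"
    anomaly_threshold: float = 1.0
    seed: int = 17
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if not (0.0 < self.path_threshold <= 1.0):
            raise ConfigError(f"path_threshold must be in (0, 1], got {self.path_threshold}")
        if self.max_path_length < 1:
            raise ConfigError(f"max_path_length must be >= 1, got {self.max_path_length}")
        if self.criticality_aggregation not in AGGREGATIONS:
            raise ConfigError(
                f"criticality_aggregation must be one of {AGGREGATIONS}, "
                f"got {self.criticality_aggregation!r}"
            )
        if self.anomaly_threshold < 0:
            raise ConfigError(f"anomaly_threshold must be >= 0, got {self.anomaly_threshold}")
        if self.verbosity not in VERBOSITY_LEVELS:
            raise ConfigError(f"verbosity must be one of {VERBOSITY_LEVELS}")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**dict(data))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8")
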