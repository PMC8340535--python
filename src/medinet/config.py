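"""Run configuration: defaults, YAML loading, provenance echo."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Numeric knobs of a ranking run; echoed into the output directory."""

    beta: float = 0.4
    alpha: float = 0.05
    fraction: float = 0.05
    q_alpha: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    aggregation: str = "median"
    combine: str = "product"
    normalization: str = "row_stochastic"

    def __post_init__(self):
        if not (0.0 < self.beta <= 1.0):
            raise ParameterError(f"beta must lie in (0, 1], got {self.beta}")
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not (0.0 < self.fraction <= 1.0):
            raise ParameterError(f"fraction must lie in (0, 1], got {self.fraction}")
        if not (0.0 < self.q_alpha <= 1.0):
            raise ParameterError(f"q_alpha must lie in (0, 1], got {self.q_alpha}")
        if self.n_perm < 0:
            raise ParameterError(f"n_perm must be non-negative, got {self.n_perm}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
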