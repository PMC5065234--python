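"""Run configuration: YAML-backed task descriptions with validation.

A RunConfig names a task, the circuit parameters, task-specific settings,
the output location, and the base seed; every run record round-trips
through serialisation so results carry full provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import CircuitParams

__all__ = ["RunConfig", "TASKS"]

TASKS = ("solve_single", "solve_dual", "sweep", "phase_map", "simulate", "mi", "fixtures")


@dataclass
class RunConfig:
    task: str
    params: CircuitParams = field(default_factory=CircuitParams)
    settings: dict = field(default_factory=dict)
    out: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "params": self.params.to_dict(),
            "settings": self.settings,
            "out": self.out,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "params" in d and not isinstance(d["params"], CircuitParams):
            try:
                d["params"] = CircuitParams.from_dict(d["params"])
            except (TypeError, ValueError) as e:
                raise ValueError(f"invalid params block: {e}") from e
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
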