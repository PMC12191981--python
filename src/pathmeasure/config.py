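"""Run configuration: validated records that round-trip through YAML/JSON."""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path as FsPath

import yaml

from .dynamics import ProcessSpec, TimeGrid
from .potentials import potential_from_spec

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """One simulation run: process, grid, ensemble size, seed, flags."""

    potential: dict
    eps: float
    dt: float
    n_steps: int
    n_paths: int = 1
    seed: int = 0
    x0: float = 0.0
    construction: str | None = None
    mode: str | None = None
    out: str | None = None

    def __post_init__(self):
        if not (self.eps > 0 and math.isfinite(self.eps)):
            raise ValueError(f"eps must be positive, got {self.eps}")
        if not (self.dt > 0 and math.isfinite(self.dt)):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.n_paths < 1:
            raise ValueError(f"n_paths must be >= 1, got {self.n_paths}")
        if self.mode is not None and self.mode not in ("discrete", "continuous"):
            raise ValueError(f"mode must be discrete|continuous, got {self.mode!r}")
        # fail early on a malformed potential spec
        potential_from_spec(self.potential)

    def grid(self) -> TimeGrid:
        return TimeGrid(dt=self.dt, n_steps=self.n_steps)

    def process(self) -> ProcessSpec:
        return ProcessSpec(potential_from_spec(self.potential), self.eps)

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def load_config(path) -> RunConfig:
    """Parse a JSON or YAML config file into a validated RunConfig."""
    path = FsPath(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ValueError(f"invalid config field in {path}: {exc}") from exc


def save_config(cfg: RunConfig, path) -> None:
    """Write a RunConfig back to disk (format chosen by extension)."""
    path = FsPath(path)
    data = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
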