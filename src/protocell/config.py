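"""Run configuration: file parsing (YAML/TOML), validation, hashing.

A :class:`RunConfig` bundles the model parameters with run-control fields
(steps, record stride, seed, output paths) and is fully serialisable, so a
run is exactly reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import Params

__all__ = ["RunConfig", "parse_config", "config_hash"]

_PARAM_KEYS = {f.name for f in dataclasses.fields(Params)}
_RUN_KEYS = {"steps", "stride", "seed", "output", "init_k",
             "replicator_fraction"}


@dataclass
class RunConfig:
    params: Params = field(default_factory=Params)
    steps: int = 10_000
    stride: int = 1_000
    seed: int = 0
    output: str | None = None
    init_k: tuple[float, float, float, float] | None = None
    replicator_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not 0 < self.replicator_fraction <= 1:
            raise ValueError("replicator_fraction must lie in (0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        p = d.pop("params")
        p["mutation_method"] = self.params.mutation_method.name
        p["symmetry_mode"] = self.params.symmetry_mode.name
        p["variant"] = self.params.variant.name
        d.update(p)
        if d["init_k"] is not None:
            d["init_k"] = list(d["init_k"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        unknown = set(data) - _PARAM_KEYS - _RUN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        pkw = {k: data.pop(k) for k in list(data) if k in _PARAM_KEYS}
        if "init_k" in data and data["init_k"] is not None:
            data["init_k"] = tuple(float(v) for v in data["init_k"])
        try:
            params = Params(**pkw)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"invalid model parameters: {exc}") from exc
        return cls(params=params, **data)

    @property
    def hash(self) -> str:
        return config_hash(self)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def parse_config(path: str | Path | None = None, /, **overrides) -> RunConfig:
    """Load a RunConfig from a YAML or TOML file; keyword overrides win.

    With no file, Table-style defaults apply (m=0.01, delta=0.05, d=0.02,
    N=50V, k bounded at 1).
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".toml", ".tml"):
            data = tomllib.loads(text)
        else:
            data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must define a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.from_dict(data)
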