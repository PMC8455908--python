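"""Run configuration: datasets, candidate effects, CV settings, seeds.

A run is a pure function of its configuration and input files; the config
hash is stamped into every output so results can be traced back to the
exact settings that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .model_space import (CandidateEffectSet, DEFAULT_INTERACTIONS,
                          DEFAULT_MAINS)

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Settings for a full score -> describe -> select -> fit -> transfer run."""

    datasets: dict[str, str]                  # name -> CSV path
    outcome: str = "harsh_discipline"
    mains: list[str] = field(default_factory=lambda: list(DEFAULT_MAINS))
    interactions: list[list[str]] = field(
        default_factory=lambda: [list(t) for t in DEFAULT_INTERACTIONS])
    K: int = 10
    repeats: int = 200
    seed: int = 0
    inverted_folds: bool = False
    max_models: int | None = None
    huber_c: float = 1.345
    output_dir: str = "harshcv_run"
    #: optional scale manifests per dataset: composite -> item columns
    manifests: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    passthrough: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.seed is None:
            raise ValueError("seed must be set explicitly")

    def effect_set(self) -> CandidateEffectSet:
        return CandidateEffectSet(tuple(self.mains),
                                  tuple(tuple(i) for i in self.interactions))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    return RunConfig(**raw)
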