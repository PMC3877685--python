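"""Run configuration with the defaults used throughout the pipeline."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import yaml

from .network_io import ValidationError

__all__ = ["Config"]


@dataclass
class Config:
    """Resolved pipeline parameters; every field can be overridden per run."""

    min_range: int = 5
    max_range: int = 15
    probeset_size: int = 5
    overlap_threshold: float = 0.6
    k: int | None = None  # None = rule of thumb round(sqrt(M/2))
    g: int = 15
    s0_policy: str | float = "median"
    seed: int = 0
    positive_label: str = "pos"

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "Config":
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
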