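"""Flat run configuration for the pipeline CLI.

The config file is a flat YAML mapping (key: value, no nesting); any CLI
flag overrides the corresponding key. Validation happens before any
computation starts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .features import ALL_FEATURES


@dataclass
class RunConfig:
    # tunnel detection
    probe_radius: float = 3.0
    burial_depth: float = 4.0
    step: float = 0.5
    cost_exponent: float = 2.0
    # alignment
    d0_floor: float = 0.5
    gap_penalty: float = 0.6
    fragment_len: int = 20
    # classifier
    svm_c: float = 1.0
    svm_gamma: str = "scale"
    subset: str = "length,curvature,tm_score"
    folds: int = 10
    members: int = 15
    seed: int = 0
    # paths
    templates_manifest: str = ""
    output_dir: str = "ssbdsb_out"

    def validate(self) -> None:
        for name in ("probe_radius", "burial_depth", "step", "cost_exponent",
                     "d0_floor", "gap_penalty", "svm_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config: {name} must be positive")
        for name in ("fragment_len", "folds", "members"):
            if getattr(self, name) < 1:
                raise ValueError(f"config: {name} must be >= 1")
        if self.members % 2 == 0:
            raise ValueError("config: members must be odd")
        names = [s.strip() for s in self.subset.split(",") if s.strip()]
        bad = set(names) - set(ALL_FEATURES)
        if not names or bad:
            raise ValueError(f"config: invalid feature subset {self.subset!r}")

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        data: dict = {}
        if path:
            with open(path) as fh:
                loaded = yaml.safe_load(fh) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: config must be a flat mapping")
            known = {f.name for f in fields(cls)}
            unknown = set(loaded) - known
            if unknown:
                raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
            data.update(loaded)
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
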