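"""Run configuration.

Defaults follow the settings used throughout the package's reference
workflow: beta = 0.1 (Lomap's default), MIN_SCORE = 0.5 for the optimal
path, a map prune threshold of 0.2, MAX_DIST = 3, MAX_CYCLE = 4,
MAX_SUBGRAPH_DIST = 4, and a series link-score threshold of 0.6.
Precedence is CLI flags > YAML config file > these defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    beta: float = 0.1
    min_score: float = 0.5  # optimal-path link-score floor
    prune_threshold: float = 0.2  # map-construction pruning floor
    max_dist: int = 3  # optimal path length bound (edges)
    max_cycle: int = 4  # largest allowed thermodynamic cycle
    max_subgraph_dist: int = 4  # A->B corridor bound for subgraph extraction
    series_threshold: float = 0.6  # series bad-edge threshold
    series_d_max: int = 6  # member-member distance bound in series maps
    max_iterations: int = 5  # series inject/rebuild/prune cap
    mcs_timeout: int = 60  # per-pair MCS search budget, seconds
    subgraph_mode: str = "finalize"  # or "each_removal"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.min_score < 1:
            raise ValueError("min_score must lie in (0, 1)")
        if not 0 <= self.prune_threshold < 1:
            raise ValueError("prune_threshold must lie in [0, 1)")
        if self.max_dist < 1:
            raise ValueError("max_dist must be >= 1")
        if self.max_cycle < 3:
            raise ValueError("max_cycle must be >= 3 (smallest possible cycle)")
        if self.max_subgraph_dist < 1:
            raise ValueError("max_subgraph_dist must be >= 1")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0 < self.series_threshold < 1:
            raise ValueError("series_threshold must lie in (0, 1)")
        if self.subgraph_mode not in ("finalize", "each_removal"):
            raise ValueError("subgraph_mode must be 'finalize' or 'each_removal'")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        """Load a YAML mapping of config keys; ``overrides`` win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


__all__ = ["RunConfig"]
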