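"""Run configuration with validated defaults.

Defaults follow the published protocol where it states them (100 submodels,
100 inner bootstraps, strict >50% stability threshold, 50 trees, 90%
minority undersampling); everything else is an explicit, documented choice.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # ensemble
    n_submodels: int = 100
    n_trees: int = 50
    undersample_fraction: float = 0.9
    empty_selection: str = "top_k"     # or "error"
    fallback_top_k: int = 5
    tie_positive: bool = False         # confidence == 0.5 -> negative label

    # stability selection
    n_inner_bootstraps: int = 100
    stability_threshold: float = 0.5
    lambda_grid_size: int = 10
    lambda_grid_ratio: float = 0.1
    min_lambda_hits: int = 1           # "selected in a run" = nonzero at >= this many lambdas

    # weighting
    ws_log_base: float = 10.0
    welch_t: bool = False
    counting_mode: str = "distinct"    # or "fitch"
    fitch_min_s: float = 0.5

    # solver
    solver_tol: float = 1e-7
    solver_max_iter: int = 5000

    # global
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_submodels < 1 or self.n_trees < 1 or self.n_inner_bootstraps < 1:
            raise ConfigError("counts must be >= 1")
        if not (0 < self.undersample_fraction <= 1):
            raise ConfigError("undersample_fraction must be in (0, 1]")
        if not (0 <= self.stability_threshold < 1):
            raise ConfigError("stability_threshold must be in [0, 1)")
        if self.lambda_grid_size < 1 or not (0 < self.lambda_grid_ratio < 1):
            raise ConfigError("bad lambda grid parameters")
        if self.min_lambda_hits < 1:
            raise ConfigError("min_lambda_hits must be >= 1")
        if self.counting_mode not in ("distinct", "fitch"):
            raise ConfigError(f"unknown counting mode {self.counting_mode!r}")
        if self.empty_selection not in ("top_k", "error"):
            raise ConfigError(f"unknown empty_selection {self.empty_selection!r}")
        if self.ws_log_base <= 1:
            raise ConfigError("ws_log_base must be > 1")

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
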