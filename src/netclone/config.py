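"""Run configuration: a flat, structured-text (YAML/JSON) record of every
parameter a simulation needs, with strict key checking and lossless
round-tripping so that result files can embed their full provenance."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .mmc import DynamicsParams, MCParams, STATIC_FULL
from .netgen import DEFAULT_BARCODE_LENGTH, DEFAULT_SPACER
from .state import CostParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # target network
    n_cells: int = 20
    density: float = 0.2
    topology: str = "er"  # er | ba
    attach_m: int = 2  # BA attachment count (used when topology == "ba")
    # barcode encoding
    barcode_length: int = DEFAULT_BARCODE_LENGTH
    spacer: str = DEFAULT_SPACER
    # cost function
    gamma: float = 2.0
    epsilon: float = 10.0
    # Monte Carlo
    temperature: float = 1e-4
    mode: str = STATIC_FULL  # static_full | dynamic_sparse
    seed: int = 0
    max_attempts: int | None = None
    check_interval: int | None = None
    enable_swaps_flips: bool = True
    target_relocations: int = 100
    # scaling grids
    sizes: list[int] = field(default_factory=lambda: [10, 16, 25, 40, 63, 100])
    densities: list[float] = field(default_factory=lambda: [0.05, 0.1, 0.2, 0.4, 0.8])
    replicates: int = 5
    # bookkeeping
    out_dir: str = "."
    log_level: str = "info"

    def cost_params(self) -> CostParams:
        return CostParams(gamma=self.gamma, epsilon=self.epsilon)

    def mc_params(self) -> MCParams:
        return MCParams(
            temperature=self.temperature,
            max_attempts=self.max_attempts,
            oboc_check_interval=self.check_interval,
            enable_swaps_flips=self.enable_swaps_flips,
            seed=self.seed,
        )

    def dynamics_params(self) -> DynamicsParams:
        return DynamicsParams(mode=self.mode, target_relocations=self.target_relocations)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Load YAML or JSON; unknown keys are rejected with their names."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    unknown = sorted(set(data) - _FIELDS)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(config.to_dict(), indent=2))
    else:
        p.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
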