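"""Run configuration: flat YAML schema, defaults, validation, hashing.

Schema (all keys optional; unspecified keys fall back to the standard
parameter set):

=================== ======================= =================================
key                 default                 meaning
=================== ======================= =================================
conditions          [1, ..., 16]            condition ids to simulate
iterations          1000000                 iterations per repetition
repetitions         10                      repetitions per condition
eps_delta           0.01                    delta-rule learning rate
eps_phi             0.007454                Phi-rule learning rate
seed                0                       base seed (per-run seeds derive)
thin                10                      store every thin-th iteration
tail_window         100000                  final unthinned window
grid_resolution     101                     marching-squares grid per axis
grid_low, grid_high 0.0, 3.0                weight-space grid bounds
motivation          "default"               "default" (gaussian gate) | "constant"
stimulus_sd         0.16666666666666666     stimulus truncated-Gaussian SD
out_dir             "runs"                  output directory
=================== ======================= =================================

Flag values override file values; ``serialize(parse(x))`` round-trips to
the normalised (defaults-resolved) form.  The config hash stamps every
output file so downstream stages can refuse mismatched inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .engine import EngineConfig
from .stochastic_world import MotivationSpec, StimulusSamplingSpec, WorldConfig
from .update_rules import GridSpec
from .value_models import ConfigurationError

__all__ = ["RunConfig", "parse_config", "serialize_config", "config_hash"]

_DEFAULTS = {
    "conditions": list(range(1, 17)),
    "iterations": 1_000_000,
    "repetitions": 10,
    "eps_delta": 0.01,
    "eps_phi": 0.007454,
    "seed": 0,
    "thin": 10,
    "tail_window": 100_000,
    "grid_resolution": 101,
    "grid_low": 0.0,
    "grid_high": 3.0,
    "motivation": "default",
    "stimulus_sd": 1.0 / 6.0,
    "out_dir": "runs",
}


@dataclass
class RunConfig:
    """Validated, defaults-resolved run configuration."""

    conditions: list = field(default_factory=lambda: list(range(1, 17)))
    iterations: int = 1_000_000
    repetitions: int = 10
    eps_delta: float = 0.01
    eps_phi: float = 0.007454
    seed: int = 0
    thin: int = 10
    tail_window: int = 100_000
    grid_resolution: int = 101
    grid_low: float = 0.0
    grid_high: float = 3.0
    motivation: str = "default"
    stimulus_sd: float = 1.0 / 6.0
    out_dir: str = "runs"

    def engine_config(self) -> EngineConfig:
        return EngineConfig(
            n_iterations=self.iterations,
            n_repetitions=self.repetitions,
            eps_delta=self.eps_delta,
            eps_phi=self.eps_phi,
            thin=self.thin,
            tail_window=self.tail_window,
            grid=GridSpec(self.grid_low, self.grid_high, self.grid_resolution),
        )

    def world_config(self) -> WorldConfig:
        motivation = (
            MotivationSpec(form="constant")
            if self.motivation == "constant"
            else MotivationSpec()
        )
        return WorldConfig(
            stimulus=StimulusSamplingSpec(sd=self.stimulus_sd), motivation=motivation
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = [int(c) for c in d["conditions"]]
        return d


def parse_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a flat YAML config file and/or apply overrides; validate fully."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("config file must be a flat key/value mapping")
        raw.update(loaded)
    for k, v in (overrides or {}).items():
        if v is not None:
            raw[k] = v

    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ConfigurationError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(_DEFAULTS)}"
        )
    merged = {**_DEFAULTS, **raw}
    if isinstance(merged["conditions"], int):
        merged["conditions"] = [merged["conditions"]]
    conditions = [int(c) for c in merged["conditions"]]
    for c in conditions:
        if not 1 <= c <= 16:
            raise ConfigurationError(f"condition id {c} out of range; valid ids are 1..16")
    if merged["motivation"] not in ("default", "constant"):
        raise ConfigurationError('motivation must be "default" or "constant"')
    for key in ("eps_delta", "eps_phi"):
        if float(merged[key]) <= 0:
            raise ConfigurationError(f"{key} must be > 0, got {merged[key]}")
    cfg = RunConfig(
        conditions=conditions,
        iterations=int(merged["iterations"]),
        repetitions=int(merged["repetitions"]),
        eps_delta=float(merged["eps_delta"]),
        eps_phi=float(merged["eps_phi"]),
        seed=int(merged["seed"]),
        thin=int(merged["thin"]),
        tail_window=int(merged["tail_window"]),
        grid_resolution=int(merged["grid_resolution"]),
        grid_low=float(merged["grid_low"]),
        grid_high=float(merged["grid_high"]),
        motivation=str(merged["motivation"]),
        stimulus_sd=float(merged["stimulus_sd"]),
        out_dir=str(merged["out_dir"]),
    )
    cfg.engine_config()  # validates engine-side invariants
    return cfg


def serialize_config(cfg: RunConfig) -> str:
    """Canonical YAML form (sorted keys, defaults resolved)."""
    return yaml.safe_dump(cfg.to_dict(), sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the normalised configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
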