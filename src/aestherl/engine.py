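"""Simulation engine: the 16 experimental conditions and seeded runs.

A *condition* pairs one of four generating reward models with one of four
value functions and an update rule, in four sets of four:

=============== ============== =================== =====================
set             reward model   value function      update direction
=============== ============== =================== =====================
purely_linear   each of four   linear              gradient of linear
mixed_linear    each of four   matched to reward   gradient of linear
full_gradient   each of four   matched to reward   gradient of matched
shortest_path   each of four   matched to reward   Phi (toward isoline)
=============== ============== =================== =====================

Conditions 1, 5, and 9 are byte-identical specifications (linear reward,
linear value, linear gradient).

Each run iterates: sample stimulus -> sample reward -> compute mean
motivation -> update weights, starting from w = (0, 0).  Runs are fully
deterministic given their seed.  The recorded learning signal is
``delta = m_bar * (r* - mu)``, the motivation-gated regret.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .stochastic_world import (
    WorldConfig,
    mean_motivation,
    mean_reward,
    sample_stimulus,
    standard_reward_model,
)
from .update_rules import GridSpec, UpdateRuleSpec, apply_update
from .value_models import (
    STANDARD_CONSTANTS,
    ConfigurationError,
    ValueFunctionSpec,
)

__all__ = [
    "ConditionSpec",
    "EngineConfig",
    "Trajectory",
    "CONDITION_SETS",
    "build_condition",
    "run_simulation",
    "run_experiment",
]

_KINDS = ("linear", "output_saturation", "component_saturation", "aleem")
CONDITION_SETS = ("purely_linear", "mixed_linear", "full_gradient", "shortest_path")


@dataclass(frozen=True)
class ConditionSpec:
    """One row of the 16-condition design."""

    id: int
    set_name: str
    reward_kind: str
    value_kind: str
    rule: str  # "gradient" | "phi"
    gradient_source: str | None  # value kind whose gradient is followed


def build_condition(cond_id: int) -> ConditionSpec:
    """Condition ``cond_id`` in 1..16 (see module docstring for the design)."""
    if not 1 <= int(cond_id) <= 16:
        raise ConfigurationError(f"condition id must be in 1..16, got {cond_id}")
    cond_id = int(cond_id)
    set_idx, kind_idx = divmod(cond_id - 1, 4)
    set_name = CONDITION_SETS[set_idx]
    reward_kind = _KINDS[kind_idx]
    if set_name == "purely_linear":
        value_kind, rule, gsrc = "linear", "gradient", "linear"
    elif set_name == "mixed_linear":
        value_kind, rule, gsrc = reward_kind, "gradient", "linear"
    elif set_name == "full_gradient":
        value_kind, rule, gsrc = reward_kind, "gradient", reward_kind
    else:
        value_kind, rule, gsrc = reward_kind, "phi", None
    return ConditionSpec(cond_id, set_name, reward_kind, value_kind, rule, gsrc)


@dataclass(frozen=True)
class EngineConfig:
    """Run-length, learning-rate, and storage settings (standard defaults)."""

    n_iterations: int = 1_000_000
    n_repetitions: int = 10
    eps_delta: float = 0.01
    eps_phi: float = 0.007454
    w0: tuple[float, float] = (0.0, 0.0)
    thin: int = 10  # keep every thin-th iteration before the tail
    tail_window: int = 100_000  # final window always stored unthinned
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_repetitions < 1:
            raise ConfigurationError("iteration and repetition counts must be >= 1")
        if self.eps_delta < 0 or self.eps_phi < 0:
            raise ConfigurationError("learning rates must be >= 0")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")


_META_KEYS = ("condition_id", "seed", "n_iterations", "thin", "tail_stored", "phi_fallbacks")


@dataclass
class Trajectory:
    """Stored (possibly thinned) record of one simulation run.

    Rows before the final tail window keep every ``thin``-th iteration;
    the final ``tail_stored`` iterations are stored unthinned (the metrics
    need them contiguous).  ``t`` holds 1-based iteration numbers of the
    stored rows.
    """

    t: np.ndarray
    w: np.ndarray
    delta: np.ndarray
    u: np.ndarray
    r_star: np.ndarray
    m_bar: np.ndarray
    condition_id: int
    seed: int
    n_iterations: int
    thin: int
    tail_stored: int
    phi_fallbacks: int = 0

    def __len__(self) -> int:
        return len(self.t)

    def tail(self) -> slice:
        """Slice of the contiguous, unthinned final window."""
        return slice(len(self.t) - self.tail_stored, len(self.t))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "w1": self.w[:, 0],
                "w2": self.w[:, 1],
                "delta": self.delta,
                "u_b": self.u[:, 0],
                "u_c": self.u[:, 1],
                "r_star": self.r_star,
                "m_bar": self.m_bar,
            }
        )

    def save_csv(self, path, extra_meta: dict | None = None) -> None:
        meta = {k: int(getattr(self, k)) for k in _META_KEYS}
        if extra_meta:
            meta.update(extra_meta)
        buf = io.StringIO()
        buf.write("# " + json.dumps(meta) + "\n")
        self.to_frame().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def load_csv(cls, path) -> "Trajectory":
        with open(path) as fh:
            header = fh.readline()
        meta = json.loads(header.lstrip("# ").strip())
        df = pd.read_csv(path, comment="#")
        return cls(
            t=df["t"].to_numpy(np.int64),
            w=df[["w1", "w2"]].to_numpy(float),
            delta=df["delta"].to_numpy(float),
            u=df[["u_b", "u_c"]].to_numpy(float),
            r_star=df["r_star"].to_numpy(float),
            m_bar=df["m_bar"].to_numpy(float),
            **{k: int(meta[k]) for k in _META_KEYS},
        )


def _value_spec_for(cond: ConditionSpec, reward_spec) -> ValueFunctionSpec:
    if cond.value_kind == reward_spec.kind:
        constants = reward_spec.constants
    else:
        constants = STANDARD_CONSTANTS[cond.value_kind]
    return ValueFunctionSpec(cond.value_kind, constants)


def run_simulation(
    cond: ConditionSpec,
    cfg: EngineConfig = EngineConfig(),
    world: WorldConfig | None = None,
    seed: int = 0,
) -> Trajectory:
    """Run one seeded simulation of a condition (algorithm: sample stimulus,
    sample reward, gate by mean motivation, update weights; repeat).

    Deterministic given ``seed``.  Raises on numeric overflow of the
    weights (does not occur at the standard learning rates).
    """
    world = world or WorldConfig()
    reward_spec = world.reward or standard_reward_model(cond.reward_kind)
    value_spec = _value_spec_for(cond, reward_spec)
    n = cfg.n_iterations
    rng = np.random.default_rng(seed)

    U = sample_stimulus(world.stimulus, rng, size=n)
    means = np.asarray(mean_reward(reward_spec, U), dtype=float)
    if reward_spec.noise_sd > 0:
        R = means + reward_spec.noise_sd * rng.standard_normal(n)
    else:
        R = means
    M = np.asarray(mean_motivation(world.motivation, U), dtype=float)
    if M.ndim == 0:
        M = np.full(n, float(M))

    W = np.empty((n, 2))
    D = np.empty(n)
    fallbacks = 0
    vkind = _kernels.KIND_CODES[value_spec.kind]
    vc = _kernels.pack_constants(value_spec.constants)
    vtheta = value_spec.theta if value_spec.kind == "aleem" else 0.0

    if cond.rule == "gradient":
        eps = cfg.eps_delta
        gkind = _kernels.KIND_CODES[cond.gradient_source]
        if cond.gradient_source == value_spec.kind:
            gc, gtheta = vc, vtheta
        else:
            gspec = ValueFunctionSpec(
                cond.gradient_source, STANDARD_CONSTANTS[cond.gradient_source]
            )
            gc = _kernels.pack_constants(gspec.constants)
            gtheta = gspec.theta if gspec.kind == "aleem" else 0.0
        if eps == 0.0:
            W[:] = cfg.w0
            D[:] = M * (R - _mu_static(value_spec, cfg.w0, U))
        else:
            _kernels.gradient_loop(
                cfg.w0[0], cfg.w0[1], U, R, M, eps, vkind, vc, vtheta, gkind, gc, gtheta, W, D
            )
    else:  # phi
        eps = cfg.eps_phi
        if eps == 0.0:
            W[:] = cfg.w0
            D[:] = M * (R - _mu_static(value_spec, cfg.w0, U))
        elif value_spec.kind == "linear":
            _kernels.phi_linear_loop(cfg.w0[0], cfg.w0[1], U, R, M, eps, W, D)
        else:
            rule = UpdateRuleSpec(rule="phi", learning_rate=eps, grid=cfg.grid)
            counters: dict = {}
            from .value_models import evaluate_value

            w = np.asarray(cfg.w0, dtype=float)
            for i in range(n):
                mu = evaluate_value(value_spec, w, U[i])
                D[i] = M[i] * (R[i] - mu)
                w = apply_update(rule, w, U[i], R[i], M[i], value_spec, counters)
                W[i] = w
            fallbacks = counters.get("phi_fallbacks", 0)

    if not np.isfinite(W[-1]).all():
        raise FloatingPointError(
            f"weights overflowed in condition {cond.id} (seed {seed}); "
            "reduce the learning rate"
        )

    # thinned storage: every thin-th row before the tail, full tail
    tail = min(cfg.tail_window, n)
    head = n - tail
    idx = np.concatenate(
        [np.arange(cfg.thin - 1, head, cfg.thin), np.arange(head, n)]
    )
    return Trajectory(
        t=idx.astype(np.int64) + 1,
        w=W[idx],
        delta=D[idx],
        u=U[idx],
        r_star=R[idx],
        m_bar=M[idx],
        condition_id=cond.id,
        seed=int(seed),
        n_iterations=n,
        thin=cfg.thin,
        tail_stored=int(tail),
        phi_fallbacks=int(fallbacks),
    )


def _mu_static(value_spec, w0, U):
    from .value_models import evaluate_value

    return np.asarray(evaluate_value(value_spec, np.asarray(w0, float), U), dtype=float)


def repetition_seed(base_seed: int, cond_id: int, rep: int) -> int:
    """Disjoint per-run seed: base + condition * 10^4 + repetition."""
    return int(base_seed) + int(cond_id) * 10_000 + int(rep)


def run_experiment(
    condition_ids,
    cfg: EngineConfig = EngineConfig(),
    world: WorldConfig | None = None,
    base_seed: int = 0,
):
    """Run ``n_repetitions`` seeded repetitions of each condition.

    Returns ``(trajectories, manifest)`` where ``trajectories`` maps
    ``(condition_id, repetition)`` to a :class:`Trajectory` and the
    manifest records conditions, seeds, and Phi-fallback counts.
    """
    trajectories = {}
    runs = []
    for cid in condition_ids:
        cond = build_condition(cid)
        for rep in range(cfg.n_repetitions):
            seed = repetition_seed(base_seed, cond.id, rep)
            traj = run_simulation(cond, cfg, world, seed)
            trajectories[(cond.id, rep)] = traj
            runs.append(
                {
                    "condition": cond.id,
                    "set": cond.set_name,
                    "repetition": rep,
                    "seed": seed,
                    "phi_fallbacks": traj.phi_fallbacks,
                }
            )
    manifest = {
        "base_seed": int(base_seed),
        "n_iterations": cfg.n_iterations,
        "n_repetitions": cfg.n_repetitions,
        "eps_delta": cfg.eps_delta,
        "eps_phi": cfg.eps_phi,
        "runs": runs,
    }
    return trajectories, manifest
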