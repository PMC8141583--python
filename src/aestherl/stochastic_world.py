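"""Stochastic environment: stimuli, rewards, and the motivation gate.

Each learning iteration draws a stimulus ``u = (u_b, u_c)`` from a
truncated-Gaussian distribution concentrated around the centre of the unit
square, a fully-motivated reward ``r*`` from a Gaussian centred on the
generating model's mean reward, and computes the mean motivation
``m_bar(u)`` in [0, 1] that multiplicatively gates the update.

The generating reward model of kind *x* has mean reward exactly equal to
the matching value function evaluated at the model's true weights — the
optimal value function equals the conditional mean reward by construction,
which is what makes parameter recovery a well-posed question.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .value_models import (
    STANDARD_CONSTANTS,
    ConfigurationError,
    ValueFunctionSpec,
    evaluate_value,
)

__all__ = [
    "StimulusSamplingSpec",
    "RewardModelSpec",
    "MotivationSpec",
    "WorldConfig",
    "sample_stimulus",
    "mean_reward",
    "sample_reward",
    "mean_motivation",
    "STANDARD_TRUE_WEIGHTS",
    "STANDARD_NOISE_SD",
    "standard_reward_model",
]

#: True weights of the standard generating models, per kind.
STANDARD_TRUE_WEIGHTS: dict[str, tuple[float, float]] = {
    "linear": (0.6, 0.9),
    "output_saturation": (1.2, 1.8),
    "component_saturation": (1.2, 1.8),
    "aleem": (0.6, 1.0),
}

#: Reward noise SD of the standard set (common to all four kinds).
STANDARD_NOISE_SD = 0.1414


@dataclass(frozen=True)
class StimulusSamplingSpec:
    """Independent truncated Gaussians per stimulus component.

    Defaults (mean 0.5, SD 1/6, support [0, 1]) put +/-3 SD exactly at the
    bounds and reproduce the root-mean-square stimulus magnitude ~0.745
    used to scale the shortest-path learning rate.  ``sd = 0`` degenerates
    to a point mass at the mean (useful for noise-free checks).
    """

    mean: tuple[float, float] = (0.5, 0.5)
    sd: float = 1.0 / 6.0
    bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if self.sd < 0:
            raise ConfigurationError("stimulus sd must be >= 0")
        if not all(lo <= m <= hi for m in self.mean):
            raise ConfigurationError("stimulus mean must lie within bounds")


@dataclass(frozen=True)
class RewardModelSpec:
    """Generating counterpart of a value function.

    ``kind`` and ``constants`` mirror :class:`ValueFunctionSpec`;
    ``true_weights`` are the generating model's fixed weights and
    ``noise_sd`` the Gaussian reward noise SD.
    """

    kind: str
    true_weights: tuple[float, float]
    constants: tuple[float, ...] = ()
    noise_sd: float = STANDARD_NOISE_SD

    def __post_init__(self) -> None:
        # delegates kind/constants validation
        object.__setattr__(self, "_value_spec", ValueFunctionSpec(self.kind, self.constants))
        object.__setattr__(self, "true_weights", tuple(float(x) for x in self.true_weights))
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def value_spec(self) -> ValueFunctionSpec:
        """The matching value-function spec (same kind and constants)."""
        return self._value_spec  # type: ignore[attr-defined]


def standard_reward_model(kind: str) -> RewardModelSpec:
    """Reward model of the standard parameter set for the given kind."""
    if kind not in STANDARD_TRUE_WEIGHTS:
        raise ConfigurationError(f"unknown reward-model kind {kind!r}")
    return RewardModelSpec(
        kind=kind,
        true_weights=STANDARD_TRUE_WEIGHTS[kind],
        constants=STANDARD_CONSTANTS[kind],
        noise_sd=STANDARD_NOISE_SD,
    )


@dataclass(frozen=True)
class MotivationSpec:
    """Mean motivation gate ``m_bar(u)`` in [0, 1].

    ``constant`` returns 1 everywhere (no gating).  ``gaussian_complexity``
    is a Gaussian bump in the complexity component with a floor:
    ``m0 + (1 - m0) exp(-(u_c - c_m)^2 / (2 sigma_m^2))`` — motivation
    peaks at a preferred complexity and never drops below ``m0``.
    """

    form: str = "gaussian_complexity"
    floor: float = 0.2
    center: float = 0.5
    width: float = 0.25

    def __post_init__(self) -> None:
        if self.form not in ("constant", "gaussian_complexity"):
            raise ConfigurationError(f"unknown motivation form {self.form!r}")
        if not 0.0 <= self.floor <= 1.0:
            raise ConfigurationError("motivation floor must be in [0, 1]")
        if self.width <= 0:
            raise ConfigurationError("motivation width must be > 0")


@dataclass(frozen=True)
class WorldConfig:
    """Bundle of the three sampling specs used by a simulation run."""

    stimulus: StimulusSamplingSpec = field(default_factory=StimulusSamplingSpec)
    motivation: MotivationSpec = field(default_factory=MotivationSpec)
    reward: RewardModelSpec | None = None  # None -> standard model for the condition


def sample_stimulus(
    spec: StimulusSamplingSpec, rng: np.random.Generator, size: int | None = None
):
    """Draw stimuli from independent truncated Gaussians within the bounds.

    Returns shape ``(2,)`` for ``size=None``, else ``(size, 2)``.
    Deterministic given the generator state.
    """
    n = 1 if size is None else int(size)
    lo, hi = spec.bounds
    out = np.empty((n, 2))
    for j, m in enumerate(spec.mean):
        if spec.sd == 0.0:
            out[:, j] = m
        else:
            a, b = (lo - m) / spec.sd, (hi - m) / spec.sd
            out[:, j] = truncnorm.rvs(a, b, loc=m, scale=spec.sd, size=n, random_state=rng)
    return out[0] if size is None else out


def mean_reward(spec: RewardModelSpec, u):
    """Mean fully-motivated reward ``<r*>(u)`` of the generating model.

    Exactly ``evaluate_value`` of the matching value spec at the true
    weights — the identity that makes that value function optimal.
    """
    return evaluate_value(spec.value_spec, np.asarray(spec.true_weights), u)


def sample_reward(spec: RewardModelSpec, u, rng: np.random.Generator):
    """Gaussian reward draw(s): mean ``mean_reward(spec, u)``, SD ``noise_sd``.

    Unbounded; with ``noise_sd = 0`` returns the mean exactly.
    """
    mu = mean_reward(spec, u)
    if spec.noise_sd == 0.0:
        return mu
    return mu + spec.noise_sd * rng.standard_normal(np.shape(mu))


def mean_motivation(spec: MotivationSpec, u):
    """Mean motivation ``m_bar(u)`` in [0, 1] (broadcasts over stimuli)."""
    u = np.asarray(u, dtype=float)
    if spec.form == "constant":
        out = np.ones(u.shape[:-1])
        return out if out.ndim else 1.0
    uc = u[..., 1]
    out = spec.floor + (1.0 - spec.floor) * np.exp(
        -((uc - spec.center) ** 2) / (2.0 * spec.width**2)
    )
    return out if np.ndim(out) else float(out)
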