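"""The four value functions and their analytic gradients.

A value function ``mu(u : w)`` maps a two-dimensional sensory stimulus
``u = (u_b, u_c)`` (visual balance and complexity, both in [0, 1]) to a
fully-motivated value, parameterised by a free weight vector
``w = (w_1, w_2)`` that learning adjusts.  Four functional forms are
supported:

``linear``
    ``mu = w . u`` — the classic linear approximator.
``output_saturation``
    A sigmoid of the linear drive, ``tanh(alpha1 (w.u - beta1) / 2)``;
    saturates the *output* of the linear form, value in (-1, 1).
``component_saturation``
    A sum of per-component sigmoids,
    ``sum_i tanh(alpha2i (w_i u_i - beta2i) / 2)``; each sensory channel
    saturates independently, value in (-N, N).
``aleem``
    Linear in balance, Gaussian-tuned in complexity:
    ``-w1 + 2 w1 u1 + w2 (exp(-(u2 - alpha3)^2 / (2 beta3^2)) - theta)``
    with ``theta`` a normaliser making the complexity term mean-free over
    [0, 1].

The sigmoids are written as ``tanh(z/2)`` of the exponent argument — the
algebraic identity ``(e^z - 1)/(e^z + 1) = tanh(z/2)`` — which avoids
overflow of ``e^z`` for large drives.

All evaluation and gradient routines broadcast over leading axes of ``w``
and ``u`` (last axis of length 2), so a whole trajectory or a weight-space
grid can be evaluated in one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "VALUE_KINDS",
    "ValueFunctionSpec",
    "evaluate_value",
    "value_gradient",
    "theta_normalizer",
    "STANDARD_CONSTANTS",
    "standard_value_spec",
]

VALUE_KINDS = ("linear", "output_saturation", "component_saturation", "aleem")

#: Fixed constants of the standard parameter set, per kind.
#: linear: none; output_saturation: (alpha1, beta1);
#: component_saturation: (alpha21, beta21, alpha22, beta22);
#: aleem: (alpha3, beta3).
STANDARD_CONSTANTS: dict[str, tuple[float, ...]] = {
    "linear": (),
    "output_saturation": (10.0, 1.5),
    "component_saturation": (10.0, 0.6, 10.0, 0.9),
    "aleem": (0.75, 0.1),
}

_N_CONSTANTS = {
    "linear": 0,
    "output_saturation": 2,
    "component_saturation": 4,
    "aleem": 2,
}


class ConfigurationError(ValueError):
    """Invalid model specification (unknown kind, malformed constants)."""


def theta_normalizer(alpha3: float, beta3: float) -> float:
    """Normaliser ``theta(alpha3, beta3) = int_0^1 exp(-(x-alpha3)^2/(2 beta3^2)) dx``.

    Computed in closed form via the standard normal CDF,
    ``beta3 sqrt(2 pi) (Phi((1-alpha3)/beta3) - Phi(-alpha3/beta3))``,
    which is exact and cheap enough for hot loops.  Always in
    ``(0, min(1, beta3 sqrt(2 pi)))`` for ``alpha3`` in [0, 1].
    """
    if beta3 <= 0:
        raise ConfigurationError(f"beta3 must be > 0, got {beta3}")
    return float(
        beta3
        * np.sqrt(2.0 * np.pi)
        * (norm.cdf((1.0 - alpha3) / beta3) - norm.cdf(-alpha3 / beta3))
    )


@dataclass(frozen=True)
class ValueFunctionSpec:
    """One of the four value-function forms with its fixed constants.

    The free parameters ``w`` are *not* part of the spec — they are the
    quantity that learning adjusts.  Constants are positional per kind
    (see :data:`STANDARD_CONSTANTS` for the ordering).
    """

    kind: str
    constants: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in VALUE_KINDS:
            raise ConfigurationError(
                f"unknown value-function kind {self.kind!r}; expected one of {VALUE_KINDS}"
            )
        object.__setattr__(self, "constants", tuple(float(c) for c in self.constants))
        if len(self.constants) != _N_CONSTANTS[self.kind]:
            raise ConfigurationError(
                f"kind {self.kind!r} takes {_N_CONSTANTS[self.kind]} constants, "
                f"got {len(self.constants)}"
            )
        if self.kind == "output_saturation" and self.constants[0] <= 0:
            raise ConfigurationError("alpha1 must be > 0")
        if self.kind == "component_saturation" and (
            self.constants[0] <= 0 or self.constants[2] <= 0
        ):
            raise ConfigurationError("alpha21 and alpha22 must be > 0")
        if self.kind == "aleem":
            if self.constants[0] <= 0:
                raise ConfigurationError("alpha3 must be > 0")
            if self.constants[1] <= 0:
                raise ConfigurationError("beta3 must be > 0")

    @property
    def theta(self) -> float:
        """Gaussian-term normaliser (aleem kind only)."""
        if self.kind != "aleem":
            raise ConfigurationError("theta is defined only for the aleem kind")
        return theta_normalizer(*self.constants)


def standard_value_spec(kind: str) -> ValueFunctionSpec:
    """Value-function spec with the standard (Table-of-parameters) constants."""
    if kind not in VALUE_KINDS:
        raise ConfigurationError(f"unknown value-function kind {kind!r}")
    return ValueFunctionSpec(kind, STANDARD_CONSTANTS[kind])


def _split(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    return a[..., 0], a[..., 1]


def evaluate_value(spec: ValueFunctionSpec, w, u):
    """Fully-motivated value ``mu(u : w)`` for the spec's kind.

    ``w`` and ``u`` broadcast against each other over leading axes; the
    last axis must have length 2.  Returns a scalar for scalar inputs.
    """
    w = np.asarray(w, dtype=float)
    u = np.asarray(u, dtype=float)
    if spec.kind == "linear":
        out = (w * u).sum(axis=-1)
    elif spec.kind == "output_saturation":
        a1, b1 = spec.constants
        out = np.tanh(0.5 * a1 * ((w * u).sum(axis=-1) - b1))
    elif spec.kind == "component_saturation":
        a21, b21, a22, b22 = spec.constants
        w1, w2 = _split(w)
        u1, u2 = _split(u)
        out = np.tanh(0.5 * a21 * (w1 * u1 - b21)) + np.tanh(0.5 * a22 * (w2 * u2 - b22))
    else:  # aleem
        a3, b3 = spec.constants
        w1, w2 = _split(w)
        u1, u2 = _split(u)
        out = -w1 + 2.0 * w1 * u1 + w2 * (
            np.exp(-((u2 - a3) ** 2) / (2.0 * b3**2)) - spec.theta
        )
    return out if out.ndim else float(out)


def value_gradient(spec: ValueFunctionSpec, w, u):
    """Analytic gradient ``grad_w mu(u : w)``, shape ``(..., 2)``.

    For the linear kind the gradient is the stimulus vector itself.  The
    sigmoidal kinds use ``d tanh(z/2)/dz = sech^2(z/2) / 2``.
    """
    w = np.asarray(w, dtype=float)
    u = np.asarray(u, dtype=float)
    if spec.kind == "linear":
        return np.broadcast_arrays(u, w)[0].copy() if u.ndim else u
    if spec.kind == "output_saturation":
        a1, b1 = spec.constants
        z = a1 * ((w * u).sum(axis=-1) - b1)
        sech2 = 1.0 / np.cosh(0.5 * z) ** 2
        return 0.5 * a1 * sech2[..., None] * np.broadcast_arrays(u, w)[0]
    if spec.kind == "component_saturation":
        a21, b21, a22, b22 = spec.constants
        w1, w2 = _split(w)
        u1, u2 = _split(u)
        g1 = 0.5 * a21 * u1 / np.cosh(0.5 * a21 * (w1 * u1 - b21)) ** 2
        g2 = 0.5 * a22 * u2 / np.cosh(0.5 * a22 * (w2 * u2 - b22)) ** 2
        return np.stack(np.broadcast_arrays(g1, g2), axis=-1)
    # aleem
    a3, b3 = spec.constants
    u1, u2 = _split(u)
    g1 = -1.0 + 2.0 * u1
    g2 = np.exp(-((u2 - a3) ** 2) / (2.0 * b3**2)) - spec.theta
    g1, g2 = np.broadcast_arrays(g1, g2, np.asarray(w)[..., 0])[:2]
    return np.stack([g1, g2], axis=-1)
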