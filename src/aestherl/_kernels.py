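"""Numba-jitted inner loops for the simulation engine.

The sequential weight recursions cannot be vectorised (each step depends
on the previous weights), so the per-iteration scalar arithmetic is JIT
compiled.  Value-function kinds are dispatched on integer codes:
0 = linear, 1 = output_saturation, 2 = component_saturation, 3 = aleem.
Constants arrive as a padded float64 array ``c`` (layout as in
``value_models.STANDARD_CONSTANTS``) plus the precomputed ``theta``
normaliser for the aleem kind.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

KIND_CODES = {
    "linear": 0,
    "output_saturation": 1,
    "component_saturation": 2,
    "aleem": 3,
}


def pack_constants(constants) -> np.ndarray:
    c = np.zeros(4)
    c[: len(constants)] = constants
    return c


@njit(inline="always")
def _mu(kind, c, theta, w1, w2, u1, u2):
    if kind == 0:
        return w1 * u1 + w2 * u2
    if kind == 1:
        return math.tanh(0.5 * c[0] * (w1 * u1 + w2 * u2 - c[1]))
    if kind == 2:
        return math.tanh(0.5 * c[0] * (w1 * u1 - c[1])) + math.tanh(
            0.5 * c[2] * (w2 * u2 - c[3])
        )
    return -w1 + 2.0 * w1 * u1 + w2 * (
        math.exp(-((u2 - c[0]) ** 2) / (2.0 * c[1] ** 2)) - theta
    )


@njit(inline="always")
def _grad(kind, c, theta, w1, w2, u1, u2):
    if kind == 0:
        return u1, u2
    if kind == 1:
        z = c[0] * (w1 * u1 + w2 * u2 - c[1])
        s = 1.0 / math.cosh(0.5 * z) ** 2
        return 0.5 * c[0] * s * u1, 0.5 * c[0] * s * u2
    if kind == 2:
        g1 = 0.5 * c[0] * u1 / math.cosh(0.5 * c[0] * (w1 * u1 - c[1])) ** 2
        g2 = 0.5 * c[2] * u2 / math.cosh(0.5 * c[2] * (w2 * u2 - c[3])) ** 2
        return g1, g2
    g1 = -1.0 + 2.0 * u1
    g2 = math.exp(-((u2 - c[0]) ** 2) / (2.0 * c[1] ** 2)) - theta
    return g1, g2


@njit(cache=False)
def gradient_loop(w1, w2, U, R, M, eps, vkind, vc, vtheta, gkind, gc, gtheta, W, D):
    """Delta rule: w += eps * m_bar * (r* - mu) * grad_src; records w and delta."""
    n = U.shape[0]
    for i in range(n):
        u1 = U[i, 0]
        u2 = U[i, 1]
        mu = _mu(vkind, vc, vtheta, w1, w2, u1, u2)
        d = M[i] * (R[i] - mu)
        g1, g2 = _grad(gkind, gc, gtheta, w1, w2, u1, u2)
        w1 += eps * d * g1
        w2 += eps * d * g2
        W[i, 0] = w1
        W[i, 1] = w2
        D[i] = d


@njit(cache=False)
def phi_linear_loop(w1, w2, U, R, M, eps, W, D):
    """Phi rule with the exact linear projection: step along +/- u / |u|.

    For the linear value function the closest point on the target isoline
    lies along u from w, so the |regret|-toward-isoline step reduces to
    eps * m_bar * (r* - mu) * u / |u|.
    """
    n = U.shape[0]
    for i in range(n):
        u1 = U[i, 0]
        u2 = U[i, 1]
        mu = w1 * u1 + w2 * u2
        d = M[i] * (R[i] - mu)
        unorm = math.sqrt(u1 * u1 + u2 * u2)
        if unorm > 0.0:
            s = eps * d / unorm
            w1 += s * u1
            w2 += s * u2
        W[i, 0] = w1
        W[i, 1] = w2
        D[i] = d
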