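"""Parameter-update rules: gradient (delta) rule and shortest-path (Phi) rule.

Both rules move the free weights ``w`` of a value function after observing
a stimulus ``u``, a fully-motivated reward ``r*``, and the mean motivation
``m_bar``:

gradient (delta) rule
    ``w <- w + eps_delta * m_bar * (r* - mu(u:w)) * grad_w mu_src(u:w)``,
    where the gradient may come from a *different* (typically linear)
    value-function kind than the one used to evaluate ``mu`` — this is the
    mismatch the mixed-linear conditions probe.

shortest-path (Phi) rule
    the weights step toward the closest point ``w_opt`` on the *target
    isoline* — the level set ``{w_r : mu(u:w_r) = r*}`` in weight space —
    by ``eps_phi * m_bar * |r* - mu(u:w)|`` along the unit vector from
    ``w`` to ``w_opt``.  The step direction is equivalently the value
    gradient at ``w_opt`` (to which ``w_opt - w`` is proportional) signed
    by the regret, which is what makes the rule attracting on both sides
    of the isoline.

Isolines of nonlinear value functions are extracted by marching squares
on a weight-space grid (101 x 101 by default); for the linear kind the
closest point has a closed form (orthogonal projection onto a line) and
is used as an exact fast path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .value_models import ConfigurationError, ValueFunctionSpec, evaluate_value

__all__ = [
    "GridSpec",
    "IsolineSet",
    "PhiStep",
    "UpdateRuleSpec",
    "extract_isolines",
    "closest_point",
    "apply_update",
]


@dataclass(frozen=True)
class GridSpec:
    """Square weight-space grid for marching squares."""

    low: float = 0.0
    high: float = 3.0
    resolution: int = 101

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ConfigurationError("grid resolution must be >= 2 per axis")
        if not np.isfinite([self.low, self.high]).all() or self.high <= self.low:
            raise ConfigurationError("grid bounds must be finite with high > low")

    @property
    def step(self) -> float:
        return (self.high - self.low) / (self.resolution - 1)

    @property
    def cell_diagonal(self) -> float:
        return self.step * np.sqrt(2.0)

    def axis(self) -> np.ndarray:
        return np.linspace(self.low, self.high, self.resolution)


@dataclass
class IsolineSet:
    """Marching-squares level set of ``w -> mu(u:w)`` at a target level.

    ``polylines`` are ordered (k, 2) vertex arrays in weight coordinates.
    ``clamped`` records that the requested level was unattainable on the
    grid and was clamped to the nearest attainable value.
    """

    level: float
    polylines: list[np.ndarray]
    grid: GridSpec
    clamped: bool = False

    @property
    def empty(self) -> bool:
        return len(self.polylines) == 0


@dataclass(frozen=True)
class PhiStep:
    """Closest-point projection onto a target isoline."""

    w_opt: np.ndarray
    direction: np.ndarray  # unit vector w -> w_opt; zero when distance == 0
    distance: float


@dataclass(frozen=True)
class UpdateRuleSpec:
    """Which rule to apply and with what learning rate.

    ``gradient_source`` names the value-function kind whose analytic
    gradient the delta rule follows (it may differ from the evaluated
    value function); ignored by the Phi rule.  ``analytic_linear`` enables
    the exact closed-form projection when the value function is linear.
    """

    rule: str
    learning_rate: float
    gradient_source: str | None = None
    grid: GridSpec = field(default_factory=GridSpec)
    analytic_linear: bool = True

    def __post_init__(self) -> None:
        if self.rule not in ("gradient", "phi"):
            raise ConfigurationError(f"unknown update rule {self.rule!r}")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.rule == "gradient" and self.gradient_source is None:
            raise ConfigurationError("gradient rule requires a gradient_source kind")


def _grid_values(spec: ValueFunctionSpec, u, grid: GridSpec) -> np.ndarray:
    ax = grid.axis()
    w1, w2 = np.meshgrid(ax, ax, indexing="ij")
    wgrid = np.stack([w1, w2], axis=-1)
    return np.asarray(evaluate_value(spec, wgrid, np.asarray(u, dtype=float)))


def extract_isolines(
    spec: ValueFunctionSpec, u, level: float, grid: GridSpec = GridSpec()
) -> IsolineSet:
    """Marching-squares isolines of ``w -> mu(u:w)`` at ``level``.

    Returns an empty set when the level is not attained on the grid.
    Vertex coordinates are in weight units (grid indices rescaled).
    """
    vals = _grid_values(spec, u, grid)
    contours = measure.find_contours(vals, level)
    polylines = [grid.low + c * grid.step for c in contours]
    return IsolineSet(level=float(level), polylines=polylines, grid=grid)


def _extract_with_clamp(
    spec: ValueFunctionSpec, u, level: float, grid: GridSpec
) -> IsolineSet:
    """Isolines at ``level``, clamping to the nearest attainable grid value."""
    vals = _grid_values(spec, u, grid)
    vmin, vmax = float(vals.min()), float(vals.max())
    clamped = False
    lvl = float(level)
    if not (vmin < lvl < vmax):
        # nudge strictly inside the attained range so a crossing exists
        span = max(vmax - vmin, np.finfo(float).tiny)
        lvl = float(np.clip(lvl, vmin + 1e-9 * span, vmax - 1e-9 * span))
        clamped = True
    contours = measure.find_contours(vals, lvl)
    polylines = [grid.low + c * grid.step for c in contours]
    return IsolineSet(level=lvl, polylines=polylines, grid=grid, clamped=clamped)


def closest_point(w, isolines: IsolineSet) -> PhiStep:
    """Closest point on the isoline set to ``w`` (point-to-segment distance).

    Ties break deterministically by lowest polyline index, then lowest
    segment index (first strict minimum wins).
    """
    if isolines.empty:
        raise ValueError("closest_point requires a non-empty isoline set (unattainable level)")
    w = np.asarray(w, dtype=float)
    best_d2 = np.inf
    best_pt = None
    for poly in isolines.polylines:
        if len(poly) == 1:
            cand = poly
        else:
            a = poly[:-1]
            seg = poly[1:] - a
            denom = (seg * seg).sum(axis=1)
            denom[denom == 0.0] = 1.0
            tt = np.clip(((w - a) * seg).sum(axis=1) / denom, 0.0, 1.0)
            cand = a + tt[:, None] * seg
        d2 = ((cand - w) ** 2).sum(axis=1)
        i = int(np.argmin(d2))
        if d2[i] < best_d2:
            best_d2 = float(d2[i])
            best_pt = cand[i]
    dist = float(np.sqrt(best_d2))
    if dist == 0.0:
        direction = np.zeros(2)
    else:
        direction = (best_pt - w) / dist
    return PhiStep(w_opt=np.asarray(best_pt, dtype=float), direction=direction, distance=dist)


def _linear_projection(w, u, level: float) -> PhiStep:
    """Exact closest point on the line ``w_r . u = level`` (linear value)."""
    w = np.asarray(w, dtype=float)
    u = np.asarray(u, dtype=float)
    gap = (level - float(w @ u)) / float(u @ u)
    w_opt = w + gap * u
    dist = abs(gap) * float(np.sqrt(u @ u))
    direction = np.zeros(2) if dist == 0.0 else (w_opt - w) / dist
    return PhiStep(w_opt=w_opt, direction=direction, distance=dist)


def apply_update(
    rule: UpdateRuleSpec,
    w,
    u,
    r_star: float,
    m_bar: float,
    value_spec: ValueFunctionSpec,
    counters: dict | None = None,
) -> np.ndarray:
    """One weight update under the given rule; returns the new weights.

    ``counters`` (optional dict) accumulates ``"phi_fallbacks"`` — the
    number of iterations whose target level was unattainable on the grid
    and was clamped to the nearest attainable isoline.
    """
    if not 0.0 <= m_bar <= 1.0:
        raise ValueError(f"m_bar must be in [0, 1], got {m_bar}")
    w = np.asarray(w, dtype=float)
    u = np.asarray(u, dtype=float)
    mu = evaluate_value(value_spec, w, u)
    regret = r_star - mu

    if rule.rule == "gradient":
        if rule.gradient_source == value_spec.kind:
            grad_spec = value_spec
        else:
            from .value_models import standard_value_spec

            grad_spec = standard_value_spec(rule.gradient_source)
        from .value_models import value_gradient

        grad = value_gradient(grad_spec, w, u)
        return w + rule.learning_rate * m_bar * regret * grad

    # Phi rule
    if value_spec.kind == "linear" and rule.analytic_linear:
        step = _linear_projection(w, u, r_star)
    else:
        isolines = _extract_with_clamp(value_spec, u, r_star, rule.grid)
        if isolines.clamped and counters is not None:
            counters["phi_fallbacks"] = counters.get("phi_fallbacks", 0) + 1
        if isolines.empty:  # degenerate (flat) value surface: no move
            return w.copy()
        step = closest_point(w, isolines)
    # |regret| toward the isoline == signed regret along the gradient at w_opt
    return w + rule.learning_rate * m_bar * abs(regret) * step.direction
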