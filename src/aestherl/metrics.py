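"""Trajectory statistics: convergence, recovery, final estimates, and
condition comparisons.

All statistics are anchored on the *motivated value trace*
``v*(t) = mu([0.5, 0.5] : w(t))`` — the value the learner assigns to the
modal stimulus — from which:

``tau_c``  time of convergence: first iteration at which ``v*`` reaches
           90% of its steady-state (tail) median, crossing toward it.
``tau_r``  recovery time: smallest lag at which the tail autocorrelation
           of ``v*`` decays to 0.1; sets the decorrelation scale.
``delta_f``, ``w_f``  final regret and weights: medians over the last
           ``2 tau_r`` iterations (two decorrelated measurement sets).
``k``      initial slope of the phase diagram ``w2 = k w1`` fitted by
           through-origin robust regression (Tukey biweight M-estimation)
           on iterations up to ``tau_c``.
``rho``    deviation from straightness, the signed ratio
           ``(w_f2 - k w_f1) / (k w_f2 + w_f1)``: zero iff the final
           weights lie on the initial straight line, positive above it
           (complexity bias), negative below (balance bias).

Condition comparisons use one-way ANOVA with post-hoc two-sided t-tests
(uncorrected, as reported) and Kendall's tau for the tau_c/tau_r
association across conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .engine import Trajectory
from .value_models import ValueFunctionSpec, evaluate_value

__all__ = [
    "RunStatistics",
    "MODAL_STIMULUS",
    "motivated_value_trace",
    "convergence_time",
    "recovery_time",
    "final_estimates",
    "initial_slope",
    "robust_through_origin_slope",
    "straightness_deviation",
    "compute_run_statistics",
    "statistics_frame",
    "compare_conditions",
    "isoline_residence",
    "delta_direction_profile",
    "weighted_error",
]

MODAL_STIMULUS = (0.5, 0.5)


@dataclass
class RunStatistics:
    """Summary statistics of a single simulation run."""

    tau_c: int
    tau_r: int
    delta_f: float
    w_f: np.ndarray
    slope_k: float
    rho_straight: float
    converged: bool

    def as_dict(self) -> dict:
        return {
            "tau_c": self.tau_c,
            "tau_r": self.tau_r,
            "delta_f": self.delta_f,
            "w_f1": float(self.w_f[0]),
            "w_f2": float(self.w_f[1]),
            "slope_k": self.slope_k,
            "rho_straight": self.rho_straight,
            "converged": self.converged,
        }


def motivated_value_trace(traj: Trajectory, spec: ValueFunctionSpec) -> np.ndarray:
    """``v*(t) = mu(modal stimulus : w(t))`` for every stored iteration."""
    u = np.asarray(MODAL_STIMULUS, dtype=float)
    return np.asarray(evaluate_value(spec, traj.w, u), dtype=float)


def convergence_time(v, t=None, tail_window: int = 100_000) -> int:
    """First time ``v`` crosses 90% of its tail median, toward the median.

    ``v`` is the value trace (stored samples); ``t`` the matching
    iteration numbers (defaults to 0, 1, 2, ...).  The steady state is the
    median of the last ``tail_window`` samples.  The crossing direction is
    the direction of approach (upward when the trace starts below the
    median, downward when above), so traces that rise from a saturated
    start toward a near-zero steady state are timed correctly.  Returns
    the final time (flagging non-convergence) if the threshold is never
    crossed.
    """
    v = np.asarray(v, dtype=float)
    if len(v) <= tail_window:
        raise ValueError(
            f"trace length {len(v)} must exceed the tail window {tail_window}"
        )
    t = np.arange(len(v)) if t is None else np.asarray(t)
    med = float(np.median(v[-tail_window:]))
    thr = 0.9 * med
    hits = np.nonzero(v >= thr if med >= v[0] else v <= thr)[0]
    if len(hits) == 0:
        return int(t[-1])
    return int(t[hits[0]])


def recovery_time(tail_v, threshold: float = 0.1) -> int:
    """Smallest lag at which the sample autocorrelation drops to ``threshold``.

    Computed on the mean-removed tail with the biased normalisation
    (FFT-based).  A zero-variance tail is an error; if the ACF never
    decays below the threshold the window length is returned with a
    warning.
    """
    x = np.asarray(tail_v, dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        raise ValueError("recovery_time is undefined for a zero-variance tail")
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[:n]
    acf = acov / denom
    below = np.nonzero(acf[1:] <= threshold)[0]
    if len(below) == 0:
        warnings.warn("autocorrelation never decayed below threshold; capping at window length")
        return n
    return int(below[0]) + 1


def final_estimates(traj: Trajectory, tau_r: int):
    """Medians of ``delta`` and ``w`` over the final ``2 tau_r`` iterations."""
    k = 2 * int(tau_r)
    if k > traj.tail_stored:
        raise ValueError(
            f"2*tau_r = {k} exceeds the unthinned tail ({traj.tail_stored} iterations)"
        )
    delta_f = float(np.median(traj.delta[-k:]))
    w_f = np.median(traj.w[-k:], axis=0)
    return delta_f, w_f


def robust_through_origin_slope(w1, w2) -> float:
    """Through-origin slope of ``w2 = k w1`` by Tukey-biweight M-estimation."""
    import statsmodels.api as sm

    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if len(w1) < 2:
        raise ValueError("need at least 2 points to fit the initial slope")
    if np.max(np.abs(w1)) < 1e-12:
        raise ValueError("degenerate early trajectory: w1 is (numerically) all zero")
    with warnings.catch_warnings():
        # an exact linear early trajectory drives the robust scale to zero
        warnings.simplefilter("ignore")
        res = sm.RLM(w2, w1[:, None], M=sm.robust.norms.TukeyBiweight()).fit()
    return float(res.params[0])


def initial_slope(traj: Trajectory, tau_c: int) -> float:
    """Initial phase-diagram slope from all stored iterations with t <= tau_c."""
    early = traj.t <= tau_c
    return robust_through_origin_slope(traj.w[early, 0], traj.w[early, 1])


def straightness_deviation(w_f, k: float) -> float:
    """Signed deviation of the final weights from the initial straight line.

    ``rho = (w_f2 - k w_f1) / (k w_f2 + w_f1)``; zero iff ``w_f`` lies on
    the line, positive above it.  Requires ``k > 0`` and a positive
    denominator (final weights in the positive quadrant).
    """
    if not k > 0:
        raise ValueError(f"slope k must be > 0, got {k}")
    w_f = np.asarray(w_f, dtype=float)
    denom = k * w_f[1] + w_f[0]
    if denom <= 0:
        raise ValueError("non-positive denominator: final weights out of regime")
    return float((w_f[1] - k * w_f[0]) / denom)


def compute_run_statistics(
    traj: Trajectory, spec: ValueFunctionSpec
) -> RunStatistics:
    """All run statistics for one trajectory (see module docstring)."""
    v = motivated_value_trace(traj, spec)
    tail = traj.tail()
    tau_c = convergence_time(v, t=traj.t, tail_window=traj.tail_stored)
    tau_r = recovery_time(v[tail])
    delta_f, w_f = final_estimates(traj, tau_r)
    converged = tau_c < traj.t[-1]
    try:
        k = initial_slope(traj, tau_c)
        rho = straightness_deviation(w_f, k)
    except ValueError:
        k = float("nan")
        rho = float("nan")
    return RunStatistics(
        tau_c=tau_c,
        tau_r=tau_r,
        delta_f=delta_f,
        w_f=np.asarray(w_f, dtype=float),
        slope_k=k,
        rho_straight=rho,
        converged=bool(converged),
    )


def statistics_frame(stats_by_run: dict) -> pd.DataFrame:
    """Tidy frame (condition, repetition, metric, value) from
    ``{(condition_id, rep): RunStatistics}``."""
    rows = []
    for (cid, rep), rs in stats_by_run.items():
        for metric, value in rs.as_dict().items():
            rows.append(
                {"condition": cid, "repetition": rep, "metric": metric, "value": float(value)}
            )
    return pd.DataFrame(rows)


def compare_conditions(stats: pd.DataFrame) -> dict:
    """One-way ANOVA + post-hoc two-sided t-tests per metric across
    conditions, and Kendall's tau between tau_c and tau_r condition means.

    ``stats`` is the tidy frame from :func:`statistics_frame`.  The t-test
    p-values are reported uncorrected.
    """
    out: dict = {"metrics": {}, "pairwise": {}}
    conditions = sorted(stats["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions to compare")
    for metric in ("delta_f", "tau_c", "tau_r", "w_f1", "w_f2", "rho_straight"):
        sub = stats[stats["metric"] == metric]
        if sub.empty:
            continue
        groups = [
            sub.loc[sub["condition"] == c, "value"].to_numpy() for c in conditions
        ]
        if any(len(g) < 2 for g in groups):
            raise ValueError(f"metric {metric}: every condition needs >= 2 values")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = sstats.f_oneway(*groups)
        if not np.isfinite(F):  # identical groups: zero between-group variance
            F, p = 0.0, 1.0
        out["metrics"][metric] = {"anova_F": float(F), "anova_p": float(p)}
        pw = {}
        for i, ci in enumerate(conditions):
            for cj in conditions[i + 1 :]:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    tstat, tp = sstats.ttest_ind(
                        groups[i], groups[conditions.index(cj)]
                    )
                pw[f"{ci}-{cj}"] = {
                    "t": float(tstat) if np.isfinite(tstat) else 0.0,
                    "p": float(tp) if np.isfinite(tp) else 1.0,
                }
        out["pairwise"][metric] = pw
    # tau_c vs tau_r across conditions (per-condition means)
    tc = stats[stats["metric"] == "tau_c"].groupby("condition")["value"].mean()
    tr = stats[stats["metric"] == "tau_r"].groupby("condition")["value"].mean()
    if len(tc) >= 2:
        tau, p = sstats.kendalltau(tc.to_numpy(), tr.reindex(tc.index).to_numpy())
        out["kendall_tau_c_tau_r"] = {"tau": float(tau), "p": float(p)}
    return out


def isoline_residence(traj: Trajectory, spec: ValueFunctionSpec, window: slice | None = None):
    """Run lengths of consecutive iterations before / beyond the target isoline.

    Per stored iteration the side is ``sign(mu(u:w) - r*)``: negative
    (value underestimates the sampled reward) is *before* the isoline,
    positive is *beyond*.  Returns ``(before_runs, beyond_runs)`` arrays
    of consecutive same-side run lengths.
    """
    window = window if window is not None else traj.tail()
    mu = np.asarray(
        evaluate_value(spec, traj.w[window], traj.u[window]), dtype=float
    )
    beyond = mu > traj.r_star[window]
    # run-length encode
    change = np.nonzero(np.diff(beyond))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(beyond)]])
    lengths = ends - starts
    sides = beyond[starts]
    return lengths[~sides], lengths[sides]


def delta_direction_profile(traj: Trajectory, window: slice):
    """Stimulus direction angle vs. recorded regret over a window.

    Returns ``(angles, deltas, rank_corr)`` where ``angles = atan2(u_c,
    u_b)`` and ``rank_corr`` is the Spearman rank correlation between
    angle and regret (zero when regret is direction-blind).
    """
    u = traj.u[window]
    d = traj.delta[window]
    if len(d) == 0:
        raise ValueError("empty window")
    angles = np.arctan2(u[:, 1], u[:, 0])
    rho = float(sstats.spearmanr(angles, d).statistic)
    return angles, d, rho


def weighted_error(traj: Trajectory, window: slice) -> float:
    """Motivation-weighted squared error ``<m_bar (r* - mu)^2>`` over a window.

    Recovered from the stored learning signal: ``delta = m_bar (r* - mu)``
    implies ``m_bar (r* - mu)^2 = delta^2 / m_bar`` (zero where the
    motivation vanishes).
    """
    d = traj.delta[window]
    m = traj.m_bar[window]
    if len(d) == 0:
        raise ValueError("empty window")
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(m > 0, d * d / np.where(m > 0, m, 1.0), 0.0)
    return float(e.mean())
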