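"""Trajectory statistics: convergence/recovery times, final estimates,
straightness, and cross-condition comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import lfilter

from aestherl import (
    compare_conditions,
    compute_run_statistics,
    convergence_time,
    delta_direction_profile,
    final_estimates,
    initial_slope,
    isoline_residence,
    motivated_value_trace,
    recovery_time,
    standard_value_spec,
    straightness_deviation,
    weighted_error,
)
from aestherl.metrics import robust_through_origin_slope

LIN = standard_value_spec("linear")


class TestMotivatedValueTrace:
    def test_linear_hand_value(self, make_trajectory):
        traj = make_trajectory([[0.6, 0.9], [0.0, 0.0]])
        v = motivated_value_trace(traj, LIN)
        np.testing.assert_allclose(v, [0.75, 0.0])

    def test_output_saturation_bounded(self, make_trajectory, rng):
        spec = standard_value_spec("output_saturation")
        traj = make_trajectory(rng.normal(scale=3, size=(50, 2)))
        v = motivated_value_trace(traj, spec)
        # strict bound (-1, 1) saturates to +/-1 in floating point
        assert np.all(np.abs(v) <= 1.0)


class TestConvergenceTime:
    def test_step_trace(self):
        v = np.concatenate([np.zeros(100), np.ones(300)])
        assert convergence_time(v, tail_window=200) == 100

    def test_exponential_trace_closed_form(self):
        tau = 500.0
        t = np.arange(40_000)
        v = 1.0 - np.exp(-t / tau)
        got = convergence_time(v, tail_window=5000)
        assert got == pytest.approx(tau * np.log(10), abs=2)

    def test_constant_positive_trace(self):
        v = np.full(1000, 2.5)
        assert convergence_time(v, tail_window=100) == 0

    def test_negative_steady_state_crosses_downward(self):
        v = np.concatenate([np.zeros(50), -np.ones(450)])
        assert convergence_time(v, tail_window=100) == 50

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            convergence_time(np.ones(50), tail_window=100)


class TestRecoveryTime:
    def test_ar1_tail(self):
        """AR(1) with coefficient 0.9: the ACF decays to 0.1 at lag
        ceil(log 0.1 / log 0.9) = 22."""
        rng = np.random.default_rng(123)
        x = lfilter([1.0], [1.0, -0.9], rng.standard_normal(2**20))
        assert recovery_time(x) == 22

    def test_white_noise_tail(self):
        rng = np.random.default_rng(7)
        assert recovery_time(rng.standard_normal(100_000)) == 1

    def test_constant_plus_spike_is_robust(self):
        x = np.zeros(10_000)
        x[5000] = 1.0
        assert recovery_time(x) <= 2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            recovery_time(np.ones(1000))


class TestFinalEstimates:
    def test_constant_tail(self, make_trajectory):
        traj = make_trajectory(np.tile([0.6, 0.9], (100, 1)), delta=np.full(100, 0.3))
        d, w = final_estimates(traj, tau_r=10)
        assert d == 0.3
        np.testing.assert_allclose(w, [0.6, 0.9])

    def test_median_ignores_outlier(self, make_trajectory):
        delta = np.zeros(100)
        delta[-1] = 50.0
        traj = make_trajectory(np.zeros((100, 2)), delta=delta)
        d, _ = final_estimates(traj, tau_r=20)
        assert d == 0.0

    def test_window_exceeding_tail_rejected(self, make_trajectory):
        traj = make_trajectory(np.zeros((100, 2)), tail_stored=40)
        with pytest.raises(ValueError):
            final_estimates(traj, tau_r=30)


class TestInitialSlope:
    def test_exact_line(self):
        w1 = np.linspace(0.01, 1, 50)
        assert robust_through_origin_slope(w1, 2 * w1) == pytest.approx(2.0, abs=1e-9)

    def test_robust_to_gross_outliers(self, rng):
        w1 = np.linspace(0.01, 1, 200)
        w2 = 2 * w1
        idx = rng.choice(200, size=10, replace=False)
        w2[idx] += rng.uniform(3, 6, size=10)
        assert robust_through_origin_slope(w1, w2) == pytest.approx(2.0, abs=0.05)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            robust_through_origin_slope([0.5], [1.0])

    def test_degenerate_w1_rejected(self):
        with pytest.raises(ValueError):
            robust_through_origin_slope(np.zeros(10), np.linspace(0, 1, 10))

    def test_uses_only_early_iterations(self, make_trajectory):
        w1 = np.linspace(0.01, 1, 100)
        w = np.column_stack([w1, 2 * w1])
        w[60:, 1] = 5.0  # late deviation must not affect the early fit
        traj = make_trajectory(w)
        assert initial_slope(traj, tau_c=50) == pytest.approx(2.0, abs=1e-6)


class TestStraightnessDeviation:
    def test_on_line_is_zero(self):
        for k in (0.5, 1.0, 2.0):
            assert straightness_deviation([1.0, k], k) == pytest.approx(0.0)

    def test_unit_case(self):
        assert straightness_deviation([0.0, 1.0], 1.0) == pytest.approx(1.0)

    def test_one_third_case(self):
        assert straightness_deviation([1.0, 2.0], 1.0) == pytest.approx(1.0 / 3.0)

    def test_antisymmetry_under_reflection(self, rng):
        """Reflecting the final weights across the fitted line flips the
        sign of the deviation."""
        for _ in range(20):
            k = float(rng.uniform(0.3, 3.0))
            w = rng.uniform(0.2, 2.0, size=2)
            d = np.array([1.0, k]) / np.hypot(1.0, k)
            w_ref = 2 * (w @ d) * d - w
            if k * w_ref[1] + w_ref[0] <= 0:
                continue
            assert straightness_deviation(w_ref, k) == pytest.approx(
                -straightness_deviation(w, k)
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            straightness_deviation([1.0, 1.0], -1.0)
        with pytest.raises(ValueError):
            straightness_deviation([-2.0, 1.0], 1.0)


class TestCompareConditions:
    @staticmethod
    def _tidy(groups_by_metric):
        rows = []
        for metric, groups in groups_by_metric.items():
            for cid, values in groups.items():
                for rep, v in enumerate(values):
                    rows.append(
                        {"condition": cid, "repetition": rep, "metric": metric, "value": v}
                    )
        return pd.DataFrame(rows)

    def test_identical_groups_give_zero_f(self):
        df = self._tidy({"delta_f": {1: [1.0, 2.0, 3.0], 2: [1.0, 2.0, 3.0]}})
        out = compare_conditions(df)
        assert out["metrics"]["delta_f"]["anova_F"] == pytest.approx(0.0)

    def test_anova_hand_fixture(self):
        # groups [1,2,3] and [2,3,4]: SSB=1.5 (df 1), MSW=1 (df 4) -> F=1.5
        df = self._tidy({"delta_f": {1: [1.0, 2.0, 3.0], 2: [2.0, 3.0, 4.0]}})
        out = compare_conditions(df)
        assert out["metrics"]["delta_f"]["anova_F"] == pytest.approx(1.5)

    def test_ttest_hand_fixture(self):
        # pooled SD 1, mean difference -1, n=3 each: t = -1 / sqrt(2/3)
        df = self._tidy({"delta_f": {1: [1.0, 2.0, 3.0], 2: [2.0, 3.0, 4.0]}})
        out = compare_conditions(df)
        assert out["pairwise"]["delta_f"]["1-2"]["t"] == pytest.approx(-np.sqrt(1.5))

    def test_kendall_tau_four_point_fixture(self):
        # tau_c=[1,2,3,4] vs tau_r=[1,3,2,4]: 5 concordant, 1 discordant -> 2/3
        df = self._tidy(
            {
                "tau_c": {c: [v, v] for c, v in zip([1, 2, 3, 4], [1.0, 2.0, 3.0, 4.0])},
                "tau_r": {c: [v, v] for c, v in zip([1, 2, 3, 4], [1.0, 3.0, 2.0, 4.0])},
            }
        )
        out = compare_conditions(df)
        assert out["kendall_tau_c_tau_r"]["tau"] == pytest.approx(2.0 / 3.0)

    def test_perfect_concordance(self):
        df = self._tidy(
            {
                "tau_c": {c: [float(c)] * 2 for c in range(1, 6)},
                "tau_r": {c: [2.0 * c] * 2 for c in range(1, 6)},
            }
        )
        out = compare_conditions(df)
        assert out["kendall_tau_c_tau_r"]["tau"] == pytest.approx(1.0)

    def test_degenerate_groups_rejected(self):
        df = self._tidy({"delta_f": {1: [1.0], 2: [2.0, 3.0]}})
        with pytest.raises(ValueError):
            compare_conditions(df)


class TestIsolineResidence:
    def test_always_underestimating_is_one_before_run(self, make_trajectory):
        n = 50
        traj = make_trajectory(np.zeros((n, 2)), r_star=np.ones(n))
        before, beyond = isoline_residence(traj, LIN)
        assert len(beyond) == 0
        np.testing.assert_array_equal(before, [n])

    def test_alternating_sides_all_runs_length_one(self, make_trajectory):
        n = 40
        r = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        traj = make_trajectory(np.zeros((n, 2)), r_star=r)
        before, beyond = isoline_residence(traj, LIN)
        assert np.all(before == 1) and np.all(beyond == 1)
        assert len(before) == len(beyond) == n // 2


class TestDeltaDirectionProfile:
    def test_monotone_dependence_detected(self, make_trajectory, rng):
        u = rng.uniform(0.05, 1.0, size=(500, 2))
        angles = np.arctan2(u[:, 1], u[:, 0])
        traj = make_trajectory(np.zeros((500, 2)), delta=np.cos(angles), u=u)
        _, _, rho = delta_direction_profile(traj, slice(None))
        assert abs(rho) > 0.99

    def test_independent_delta_uncorrelated(self, make_trajectory, rng):
        u = rng.uniform(size=(2000, 2))
        traj = make_trajectory(np.zeros((2000, 2)), delta=rng.standard_normal(2000), u=u)
        _, _, rho = delta_direction_profile(traj, slice(None))
        assert abs(rho) < 0.05

    def test_empty_window_rejected(self, make_trajectory):
        traj = make_trajectory(np.zeros((10, 2)))
        with pytest.raises(ValueError):
            delta_direction_profile(traj, slice(0, 0))


class TestWeightedError:
    def test_zero_when_value_matches_reward(self, make_trajectory):
        traj = make_trajectory(np.zeros((20, 2)), delta=np.zeros(20))
        assert weighted_error(traj, slice(None)) == 0.0

    def test_zero_when_motivation_vanishes(self, make_trajectory):
        traj = make_trajectory(np.zeros((20, 2)), delta=np.zeros(20), m_bar=np.zeros(20))
        assert weighted_error(traj, slice(None)) == 0.0

    def test_single_sample(self, make_trajectory):
        # m=1, r*=1, mu=0 -> delta=1 -> weighted squared error 1
        traj = make_trajectory(np.zeros((1, 2)), delta=np.ones(1), r_star=np.ones(1))
        assert weighted_error(traj, slice(None)) == 1.0

    def test_decreases_over_learning(self):
        """For a converged run the motivation-weighted error over the last
        10% of iterations is below that over the first 10%."""
        from aestherl import EngineConfig, build_condition, run_simulation

        cfg = EngineConfig(n_iterations=50_000, tail_window=10_000)
        traj = run_simulation(build_condition(1), cfg, seed=21)
        n = len(traj)
        early = weighted_error(traj, slice(0, n // 10))
        late = weighted_error(traj, slice(n - n // 10, n))
        assert late < early


class TestRunStatisticsPipeline:
    def test_full_pipeline_on_linear_condition(self):
        from aestherl import EngineConfig, build_condition, run_simulation

        cfg = EngineConfig(n_iterations=60_000, tail_window=20_000)
        traj = run_simulation(build_condition(1), cfg, seed=31)
        rs = compute_run_statistics(traj, LIN)
        assert rs.converged
        assert 1 <= rs.tau_r <= 20_000
        assert 1 <= rs.tau_c <= 60_000
        assert rs.slope_k > 0
        np.testing.assert_allclose(rs.w_f, [0.6, 0.9], atol=0.05)

    def test_slow_convergence_pairs_with_slow_recovery(self):
        """Conditions that converge slowly also recover slowly: the
        aleem-reward gradient conditions have both larger tau_c and larger
        tau_r than their linear-reward counterparts (ordering check; the
        full cross-condition rank correlation is motivation-form dependent
        and is only reported, not asserted)."""
        from aestherl import EngineConfig, build_condition, run_simulation
        from aestherl.value_models import STANDARD_CONSTANTS, ValueFunctionSpec

        cfg = EngineConfig(n_iterations=200_000, tail_window=50_000)
        stats = {}
        for cid in (1, 8, 12):
            cond = build_condition(cid)
            traj = run_simulation(cond, cfg, seed=141 + cid * 100)
            spec = ValueFunctionSpec(cond.value_kind, STANDARD_CONSTANTS[cond.value_kind])
            stats[cid] = compute_run_statistics(traj, spec)
        for cid in (8, 12):
            assert stats[cid].tau_c > stats[1].tau_c
            assert stats[cid].tau_r > stats[1].tau_r
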