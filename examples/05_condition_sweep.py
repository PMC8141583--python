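"""A small sweep over the purely-linear conditions with a comparison report.

Runs conditions 1-4 (linear value function and linear gradient against
all four reward models) at desk scale, collects per-run statistics, and
compares the final regrets across conditions.  Only the linear reward
model yields near-zero regret; the nonlinear models are systematically
overestimated (negative regret).
"""

import numpy as np

import aestherl as al

cfg = al.EngineConfig(n_iterations=100_000, tail_window=50_000, n_repetitions=3)
trajs, manifest = al.run_experiment([1, 2, 3, 4], cfg, base_seed=3)

spec = al.standard_value_spec("linear")
stats = {key: al.compute_run_statistics(t, spec) for key, t in trajs.items()}

print(f"{'condition':<10} {'reward model':<22} {'mean delta_f':>12}")
for cid in (1, 2, 3, 4):
    cond = al.build_condition(cid)
    d = np.mean([stats[(cid, r)].delta_f for r in range(cfg.n_repetitions)])
    print(f"{cid:<10} {cond.reward_kind:<22} {d:>12.4f}")

report = al.compare_conditions(al.statistics_frame(stats))
f = report["metrics"]["delta_f"]
print()
print(f"one-way ANOVA on delta_f across conditions: F = {f['anova_F']:.1f}, "
      f"p = {f['anova_p']:.2e}")
print("A large F confirms the regrets differ by reward model: the linear")
print("learner's residual error is a property of the world's nonlinearity,")
print("not of the noise.")
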