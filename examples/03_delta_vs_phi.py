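"""Delta rule vs. shortest-path (Phi) rule on a nonlinear reward model.

The delta rule steps along the value gradient at the current weights and
is blind to the curvature of the target isoline; the Phi rule steps
straight toward the closest point on the isoline.  Here both learn the
output-saturation reward model with the matched value function (condition
10 vs. condition 14) and are compared on the motivation-weighted error.
"""

import aestherl as al

cfg = al.EngineConfig(n_iterations=20_000, tail_window=5_000)

for cid, label in ((10, "full-gradient delta rule"), (14, "shortest-path Phi rule")):
    cond = al.build_condition(cid)
    traj = al.run_simulation(cond, cfg, seed=5)
    n = len(traj)
    early = al.weighted_error(traj, slice(0, n // 10))
    late = al.weighted_error(traj, slice(n - n // 10, n))
    print(f"condition {cid:2d} ({label})")
    print(f"  weighted error, first 10%: {early:.4f}   last 10%: {late:.4f}")
    print(f"  final weights: [{traj.w[-1, 0]:.3f}, {traj.w[-1, 1]:.3f}]   "
          f"Phi fallbacks: {traj.phi_fallbacks}")

print()
print("At this desk scale the Phi rule has already pulled the error down,")
print("while the gradient rule is still crawling through the flat (saturated)")
print("region around the zero initial weights, where its gradient nearly")
print("vanishes.  'Phi fallbacks' counts iterations whose sampled reward lay")
print("outside the value range attainable on the weight grid (the target")
print("level is then clamped to the nearest attainable isoline).")
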