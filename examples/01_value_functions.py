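"""The four value functions and their gradients at the modal stimulus.

Each value function maps a stimulus u = (balance, complexity) to a
predicted reward, parameterised by free weights w.  The generating reward
model of each kind has mean reward equal to the matched value function at
its true weights, so evaluating at those weights shows the target each
learner is trying to reach.
"""

import numpy as np

import aestherl as al

u = np.array([0.5, 0.5])  # the modal (most common) stimulus

print(f"{'kind':<22} {'true weights':<12} {'mu(u:w_true)':>12}   gradient at w_true")
for kind in al.VALUE_KINDS:
    model = al.standard_reward_model(kind)
    w = np.asarray(model.true_weights)
    mu = al.evaluate_value(model.value_spec, w, u)
    g = al.value_gradient(model.value_spec, w, u)
    wtxt = f"[{w[0]:g}, {w[1]:g}]"
    print(f"{kind:<22} {wtxt:<12} {mu:>12.4f}   [{g[0]:.4f}, {g[1]:.4f}]")

print()
print("mu(u:w_true) is the mean reward a fully motivated observer receives")
print("at the modal stimulus; the gradient shows how sensitive the value is")
print("to each free weight there (for the linear kind it is u itself).")
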