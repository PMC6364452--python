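"""Evolve a seed under duplication + substitution and watch the
autocorrelation approach its analytic limit.

The model: each mutation is a substitution with probability q_0 = 0.2 or
a length-3 tandem duplication with probability q_3 = 0.8. The limit
profile solved from the rate matrix predicts where the empirical
autocorrelation of a long simulated repeat settles.
"""

import numpy as np

from smtr import (
    MutationModel,
    circular_autocorrelation,
    evolve,
    random_seed,
    stationary_profile,
)

q = np.zeros(4)
q[0], q[3] = 0.2, 0.8
model = MutationModel(q)
limit = stationary_profile(model, 7).rho

rng = np.random.default_rng(42)
seed = random_seed(3, rng)
print(f"seed: {seed}  (pattern length d=3, q0={model.q0}, q3={model.q[3]})")
print(f"{'n':>6} {'L':>7}  empirical rho[0..6]")
for n in (50, 500, 5000):
    trace = evolve(seed, model, n, rng)
    rho = circular_autocorrelation(trace.final, 7).rho
    print(f"{n:>6} {len(trace.final):>7}  " + " ".join(f"{v:.3f}" for v in rho))
print(f"{'limit':>6} {'':>7}  " + " ".join(f"{v:.3f}" for v in limit))
print()
print("Lags 3 and 6 (multiples of d) stay elevated; lags 1, 2, 4, 5 relax")
print("to the i.i.d. value 1/4, and the whole profile tightens onto the")
print("analytic limit as the number of mutations grows.")
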