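"""Estimate mutation probabilities and the mutation count from a single
simulated repeat, then compare against the ground truth.

The estimator sees only the final sequence and the pattern length d —
not the seed, the true probabilities, or the number of events.
"""

import numpy as np

from smtr import MutationModel, evolve, random_seed, smtr

q = np.zeros(5)
q[0], q[4] = 0.3, 0.7
model = MutationModel(q)
n_true = 400

rng = np.random.default_rng(7)
trace = evolve(random_seed(4, rng), model, n_true, rng)
print(f"true q0={q[0]}, q4={q[4]}, n={n_true}, final length {len(trace.final)}")

est = smtr(trace.final, d=4)
nz = np.nonzero(est.q_hat)[0]
print("estimated probabilities:")
for i in nz:
    print(f"  q_{i} = {est.q_hat[i]:.4f}")
print(f"estimated mutation count n^ = {est.n_hat:.1f}")
print(f"residual = {est.residual:.2e}, window m' = {est.config.m_prime}")
print()
print("q_0 is the substitution share of mutations; q_4, q_8, ... are the")
print("probabilities of duplications of those lengths. n^ divides the")
print("length growth by the expected length added per mutation.")
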