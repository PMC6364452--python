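"""Error metrics and the parameter-recovery simulation study.

The study design: for each mutation count n on a grid, draw a random
pattern length d, a random mutation model q (substitution probability
uniform on [0, 0.5], duplication mass Dirichlet over multiples of d) and
a random length-d seed; evolve n_s independent sequences; estimate q and
n from each sequence with the pattern length d as the only side
information. Reported per grid point: the mean L2 error ||q^ - q||_2 and
the normalized RMS error of n^,

    NRMSE(n) = (1/n) sqrt( (1/N) sum_i (n^_i - n)^2 ),

both for a single sequence per replicate and for the average of the n_s
per-sequence estimates (averaging is over estimates, not over
autocorrelations).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .estimate import smtr
from .simulate import MutationModel, evolve, random_model, random_seed


def l2_error(q_hat: np.ndarray, q: np.ndarray) -> float:
    """Euclidean distance ||q^ - q||_2, zero-padding the shorter vector."""
    q_hat = np.asarray(q_hat, dtype=float)
    q = np.asarray(q, dtype=float)
    k = max(q_hat.size, q.size)
    a = np.zeros(k)
    b = np.zeros(k)
    a[: q_hat.size] = q_hat
    b[: q.size] = q
    return float(np.linalg.norm(a - b))


def nrmse(n: float, estimates) -> float:
    """Normalized root-mean-square error of mutation-count estimates."""
    if n <= 0:
        raise ValueError("true count n must be positive")
    est = np.asarray(list(estimates), dtype=float)
    if est.size == 0:
        raise ValueError("need at least one estimate")
    return float(np.sqrt(np.mean((est - n) ** 2)) / n)


def conditional_duplication_probs(q: np.ndarray) -> np.ndarray:
    """q'_i = q_i / (1 - q_0): duplication-length probabilities given a
    duplication occurred. Defined only for q_0 < 1."""
    q = np.asarray(q, dtype=float)
    if q[0] >= 1.0:
        raise ValueError("q_0 = 1: no duplications to condition on")
    return q[1:] / (1.0 - q[0])


def subset_match_probability(n_items: int = 24, k: int = 5) -> float:
    """Probability that a uniformly random k-subset of n_items equals a
    fixed k-subset: 1 / C(n_items, k).

    Used as the null p-value for the agreement between two independent
    top-k chromosome rankings (24 human chromosomes, top 5).
    """
    return 1.0 / math.comb(n_items, k)


def run_recovery_experiment(
    n_grid=(10, 50, 100, 150, 200, 250, 300, 350, 400, 450, 500),
    N: int = 100,
    n_s: int = 5,
    d_range: tuple[int, int] = (1, 10),
    k_max: int = 5,
    q0_range: tuple[float, float] = (0.0, 0.5),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Parameter-recovery study over a grid of mutation counts.

    Returns a DataFrame with one row per grid point and columns
    ``q_l2_single``, ``q_l2_multi`` (mean L2 error of q^),
    ``nrmse_single``, ``nrmse_multi`` (NRMSE of n^). Fully deterministic
    given ``rng``.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    n_grid = list(n_grid)
    if not n_grid:
        raise ValueError("empty grid")
    rows = []
    for n in n_grid:
        l2_single, l2_multi, nh_single, nh_multi = [], [], [], []
        for _ in range(N):
            d = int(rng.integers(d_range[0], d_range[1] + 1))
            model = random_model(d, k_max=k_max, q0_range=q0_range, rng=rng)
            seed = random_seed(d, rng)
            q_hats, n_hats = [], []
            for _ in range(n_s):
                trace = evolve(seed, model, n, rng)
                est = smtr(trace.final, d=d)
                q_hats.append(est.q_hat)
                n_hats.append(est.n_hat)
            width = max(q.size for q in q_hats)
            padded = np.zeros((n_s, width))
            for i, q in enumerate(q_hats):
                padded[i, : q.size] = q
            l2_single.append(l2_error(padded[0], model.q))
            l2_multi.append(l2_error(padded.mean(axis=0), model.q))
            nh_single.append(n_hats[0])
            nh_multi.append(float(np.mean(n_hats)))
        rows.append(
            {
                "n": n,
                "q_l2_single": float(np.mean(l2_single)),
                "q_l2_multi": float(np.mean(l2_multi)),
                "nrmse_single": nrmse(n, nh_single),
                "nrmse_multi": nrmse(n, nh_multi),
                "N": N,
                "n_s": n_s,
            }
        )
    return pd.DataFrame(rows)
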