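"""Generative model of tandem-repeat evolution.

A short circular seed evolves by a sequence of random mutation events.
At each step, with probability q_0 a substitution occurs (a uniformly
chosen position changes to one of the 3 other letters uniformly), and
with probability q_l (l >= 1) a tandem duplication of length l occurs:
a uniformly chosen length-l window is copied and the copy is inserted
immediately after the template. q = (q_0, q_1, ..., q_K) are conditional
probabilities given that a mutation occurs, not per-generation rates.

Every stochastic operation takes an explicit ``numpy.random.Generator``;
there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .sequences import CircularSequence


@dataclass(frozen=True)
class MutationModel:
    """Conditional mutation probabilities q = (q_0, q_1, ..., q_K).

    q_0 is the substitution probability; q_l (l >= 1) the probability of
    a length-l tandem duplication. Entries are nonnegative and sum to 1.
    """

    q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 1 or q.size < 1:
            raise ValueError("q must be a nonempty 1-d probability vector")
        if np.any(q < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(q.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1 (got {q.sum()!r})")
        object.__setattr__(self, "q", q)

    @property
    def q0(self) -> float:
        return float(self.q[0])

    @property
    def K(self) -> int:
        """Maximum duplication length carried by the vector."""
        return int(self.q.size - 1)

    @property
    def support(self) -> list[int]:
        """P = {l > 0 : q_l > 0}, the duplication lengths that can occur."""
        return [int(i) for i in np.nonzero(self.q[1:])[0] + 1]

    def prob(self, length: int) -> float:
        """q_length, reading indices beyond K as 0."""
        return float(self.q[length]) if 0 <= length <= self.K else 0.0


@dataclass(frozen=True)
class Event:
    kind: str  # "substitution" | "duplication"
    position: int  # substitution site, or duplication template start
    length: int  # 0 for substitutions
    replacement: int | None = None  # new symbol code for substitutions


@dataclass(frozen=True)
class EvolutionTrace:
    """Complete record of one simulated history (ground truth for tests)."""

    seed: CircularSequence
    events: tuple[Event, ...]
    final: CircularSequence
    n: int

    def replay(self) -> CircularSequence:
        """Re-apply the recorded events to the seed; must equal ``final``."""
        codes = list(self.seed.codes)
        for ev in self.events:
            codes = _apply(codes, ev)
        return CircularSequence.from_codes(codes)


def _apply(codes: list[int], ev: Event) -> list[int]:
    L = len(codes)
    if ev.kind == "substitution":
        codes[ev.position % L] = ev.replacement
        return codes
    start, ell = ev.position, ev.length
    copy = [codes[(start + k) % L] for k in range(ell)]
    ins = ((start + ell - 1) % L) + 1  # immediately after the template
    codes[ins:ins] = copy
    return codes


def evolve(
    seed: CircularSequence,
    model: MutationModel,
    n: int,
    rng: np.random.Generator,
) -> EvolutionTrace:
    """Evolve ``seed`` through ``n`` random mutation events.

    Duplication length may exceed the current sequence length: the copied
    window then wraps around the circle (symbols re-read modulo L).
    """
    if n < 0:
        raise ValueError("number of events must be >= 0")
    kinds = rng.choice(model.q.size, size=n, p=model.q) if n else np.empty(0, int)
    codes = list(seed.codes)
    events: list[Event] = []
    for k in kinds:
        L = len(codes)
        if k == 0:
            pos = int(rng.integers(L))
            new = int(codes[pos] + 1 + rng.integers(3)) % 4
            ev = Event("substitution", pos, 0, new)
        else:
            start = int(rng.integers(L))
            ev = Event("duplication", start, int(k))
        codes = _apply(codes, ev)
        events.append(ev)
    final = CircularSequence.from_codes(codes)
    assert len(final) == len(seed) + sum(e.length for e in events)
    return EvolutionTrace(seed=seed, events=tuple(events), final=final, n=n)


def random_model(
    d: int,
    k_max: int = 5,
    q0_range: tuple[float, float] = (0.0, 0.5),
    rng: np.random.Generator | None = None,
) -> MutationModel:
    """Random mutation model with duplication lengths on multiples of d.

    q_0 ~ Uniform(q0_range); the remaining mass is spread over
    {d, 2d, ..., k_max*d} by a symmetric Dirichlet(1, ..., 1) draw, so
    gcd(support) is a multiple of the pattern length d.
    """
    if d < 1 or k_max < 1:
        raise ValueError("need d >= 1 and k_max >= 1")
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    q0 = float(rng.uniform(*q0_range))
    weights = rng.dirichlet(np.ones(k_max))
    q = np.zeros(k_max * d + 1)
    q[0] = q0
    q[np.arange(1, k_max + 1) * d] = (1.0 - q0) * weights
    return MutationModel(q)


def random_seed(d: int, rng: np.random.Generator) -> CircularSequence:
    """Seed of length d with i.i.d.-uniform symbols."""
    if d < 1:
        raise ValueError("seed length must be >= 1")
    return CircularSequence.from_codes(rng.integers(0, 4, size=d))
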