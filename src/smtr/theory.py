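"""Deterministic limit of the autocorrelation under duplication + substitution.

Stochastic approximation relates the per-event change of the normalized
autocorrelation rho to the linear ODE d(rho)/dt = A rho, where A is an
m x m rate matrix determined by the mutation probabilities q:

    A_r0 = 2 q0 / 3 + r q_r                 (r > 0)
    A_rj = r q_{r-j} + r q_{r+j}            (r > j > 0)
    A_rr = q0 (r - 8/3) + r q_{2r} - r      (r > 0)
    A_rj = r q_{r+j}                        (j > r > 0)
    A_0j = 0

(q indices beyond K read as 0). rho_n converges almost surely to the
null space of A. With substitutions (q0 > 0) the null space is a line
and the limit profile is the unique null vector with rho^0 = 1, whose
entries at lags not divisible by d = gcd{l : q_l > 0} equal 1/4. Without
substitutions (q0 = 0) the null space has dimension floor(d/2) + 1 and
the sequence becomes approximately periodic with period d — the gcd, not
the shortest or most common duplication length.

The module also provides exact brute-force oracles for the expected
one-event change of the unnormalized autocorrelation R, obtained by
enumerating every possible mutation; they validate the closed-form drift

    h_l^r(rho) = -8/3 rho^r + 2/3        (l = 0, substitution)
    h_l^r(rho) = r rho^{r-l} - r rho^r   (l > 0, duplication)

where the expected R-change is delta_l = h_l + l*rho. The substitution
form is exact at every lag; the duplication form holds up to an O(1/L)
remainder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .sequences import AutocorrelationProfile, CircularSequence, circular_autocorrelation
from .simulate import MutationModel


@dataclass(frozen=True)
class RateMatrix:
    """The ODE rate matrix A together with the model it was built from."""

    A: np.ndarray
    model: MutationModel

    @property
    def m(self) -> int:
        return int(self.A.shape[0])


def build_rate_matrix(model: MutationModel, m: int) -> RateMatrix:
    """Assemble the m x m autocorrelation rate matrix A for ``model``."""
    if m < 2:
        raise ValueError("need m >= 2")
    q0 = model.q0
    qf = model.prob
    A = np.zeros((m, m))
    for r in range(1, m):
        A[r, 0] = 2.0 * q0 / 3.0 + r * qf(r)
        for j in range(1, m):
            if r > j:
                A[r, j] = r * qf(r - j) + r * qf(r + j)
            elif r == j:
                A[r, j] = q0 * (r - 8.0 / 3.0) + r * qf(2 * r) - r
            else:
                A[r, j] = r * qf(r + j)
    return RateMatrix(A=A, model=model)


def drift(model: MutationModel, rho: AutocorrelationProfile) -> np.ndarray:
    """Right-hand side of the autocorrelation ODE evaluated at ``rho``.

    Component r (r >= 1) is
        q0 (-8/3 rho^r + 2/3) + r * sum_{l>0} q_l rho^{r-l} - (1-q0) r rho^r,
    with negative lags resolved by symmetry rho^{-k} = rho^k. Component 0
    is 0 (rho^0 is identically 1).
    """
    m = rho.m
    q0 = model.q0
    out = np.zeros(m)
    for r in range(1, m):
        acc = q0 * (-8.0 / 3.0 * rho.at(r) + 2.0 / 3.0)
        dup = 0.0
        for ell in range(1, model.K + 1):
            if model.q[ell] == 0.0:
                continue
            dup += model.q[ell] * rho.at(r - ell)  # .at raises if unavailable
        acc += r * dup - (1.0 - q0) * r * rho.at(r)
        out[r] = acc
    return out


def _autocorr_counts(codes: np.ndarray, m: int) -> np.ndarray:
    """Unnormalized R^r for r = 0..m-1 by direct comparison (exact)."""
    L = codes.size
    return np.array(
        [int(np.sum(codes == np.roll(codes, -r))) for r in range(m)], dtype=float
    )


def oracle_substitution_drift(s: CircularSequence, m: int) -> np.ndarray:
    """Exact E[R_{n+1} - R_n] under one uniform substitution.

    Enumerates all L positions x 3 replacement symbols. Agrees exactly
    with the closed form -8/3 rho^r + 2/3 at every lag 1 <= r <= L-1.
    """
    L = len(s)
    if L < 3:
        raise ValueError("need L >= 3")
    base = _autocorr_counts(s.codes, m)
    total = np.zeros(m)
    for p in range(L):
        old = s.codes[p]
        for shift in (1, 2, 3):
            mutant = s.codes.copy()
            mutant[p] = (old + shift) % 4
            total += _autocorr_counts(mutant, m) - base
    return total / (3 * L)


def oracle_duplication_drift(s: CircularSequence, ell: int, m: int) -> np.ndarray:
    """Exact E[R_{n+1} - R_n] under one uniform-start length-``ell`` duplication.

    Enumerates all L start positions. Enumeration shows the closed form
    r rho^{r-ell} - r rho^r + ell rho^r reproduces this expectation to
    machine precision (lags reduced modulo L): the O(1/L) remainder of
    the stochastic recursion enters through the length normalization
    rho = R/L, not through this conditional expectation.
    """
    L = len(s)
    if not 1 <= ell <= L:
        raise ValueError("need 1 <= ell <= L")
    base = _autocorr_counts(s.codes, m)
    total = np.zeros(m)
    for start in range(L):
        copy = s.codes[(start + np.arange(ell)) % L]
        ins = ((start + ell - 1) % L) + 1
        mutant = np.concatenate([s.codes[:ins], copy, s.codes[ins:]])
        total += _autocorr_counts(mutant, m) - base
    return total / L


def stationary_profile(model: MutationModel, m: int) -> AutocorrelationProfile:
    """The unique limit profile rho_inf with A rho_inf = 0 and rho^0 = 1.

    Requires q0 > 0 (with q0 = 0 the null space is multi-dimensional and
    the limit depends on the seed; see :func:`null_space_basis`). Solved
    as a bordered linear system — impose rho^0 = 1 and solve rows
    1..m-1 — which is deterministic and exactly reproducible.
    """
    if model.q0 <= 0.0:
        raise ValueError(
            "q0 = 0 has a multi-dimensional limit set; use null_space_basis"
        )
    A = build_rate_matrix(model, m).A
    try:
        tail = np.linalg.solve(A[1:, 1:], -A[1:, 0])
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular stationarity system at m={m}: {exc}") from None
    rho = np.concatenate([[1.0], tail])
    return AutocorrelationProfile(rho=rho, L=None)


def null_space_basis(model: MutationModel, m: int) -> list[np.ndarray]:
    """Orthonormal basis of Null(A) in the pure-duplication regime q0 = 0.

    The dimension is floor(d/2) + 1 where d = gcd of the duplication
    support; the span equals that of the lag-class indicator vectors
    v_i (1 at lags congruent to +/- i mod d). Rank decisions use a
    singular-value cutoff of 1e-10 relative to the largest singular value.
    """
    if model.q0 > 0.0:
        raise ValueError("q0 > 0 gives a one-dimensional null space; "
                         "use stationary_profile")
    A = build_rate_matrix(model, m).A
    basis = scipy.linalg.null_space(A, rcond=1e-10)
    return [basis[:, j] for j in range(basis.shape[1])]


def lag_class_vector(i: int, d: int, m: int) -> np.ndarray:
    """Indicator vector v_i: 1 at lags j with j = +/- i (mod d), else 0."""
    j = np.arange(m)
    return ((j % d == i % d) | ((-j) % d == i % d)).astype(float)


def duplication_period(model: MutationModel) -> int:
    """gcd of the duplication support — the period the sequence tends to.

    Notably this is the gcd, not the most common duplication length:
    lengths {4, 6} drive the sequence toward period 2.
    """
    support = model.support
    if not support:
        raise ValueError("no duplication length has positive probability")
    return math.gcd(*support) if len(support) > 1 else support[0]
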