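"""SMTR inverse problem: mutation probabilities from one observed repeat.

Near stationarity the autocorrelation profile rho of the observed
sequence satisfies a linear system C q = rho~ in the unknown mutation
probabilities, with

    C_r0 = 2/3 + (r - 8/3) rho^r,   C_ri = r rho^{|i-r|} (i >= 1),
    rho~_r = r rho^r,               r = 1..m'', i = 0..m',

obtained by rearranging the stationarity condition A rho = 0. The
estimate q^ solves the constrained least-squares problem

    min ||C' q - rho~||_2^2   s.t.  sum q = 1,  q >= 0,

optionally with the expected-length constraint
sum_k (k d) q_{k d} >= 1 (each mutation adds at least 1 on average),
which bounds the mutation-count estimate

    n^ = (L_final - L_seed) / sum_i i q^_i

by the observed length growth. When the pattern length d is known, the
probabilities at lengths not divisible by d are fixed to 0, the limit
value 1/4 is substituted at off-period lags, and only rows/columns with
indices divisible by d are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .sequences import AutocorrelationProfile, CircularSequence, circular_autocorrelation

#: Fixed ridge added to the least-squares objective purely as a
#: deterministic tie-break: when the fit is degenerate (e.g. perfect
#: repeats, where any simplex point with q0 = 0 fits exactly) the solver
#: returns the minimum-norm point of the optimal face.
_RIDGE = 1e-9


@dataclass(frozen=True)
class EstimationConfig:
    """Window sizes and options for one estimation run.

    m_prime: largest candidate duplication length (number of unknowns
    is m_prime + 1); m_dprime: number of equations (rows r = 1..m'');
    d: pattern length if known; enforce_length_constraint defaults to
    "on iff d is known" (the constraint as written is indexed by
    multiples of d).
    """

    m_prime: int
    m_dprime: int
    d: int | None = None
    enforce_length_constraint: bool | None = None
    tol: float = 1e-9

    def __post_init__(self):
        if self.m_prime < 1 or self.m_dprime < 1:
            raise ValueError("window sizes must be >= 1")
        if self.enforce_length_constraint is None:
            object.__setattr__(self, "enforce_length_constraint", self.d is not None)


@dataclass(frozen=True)
class EstimationResult:
    """Estimated probabilities and mutation count for one sequence."""

    q_hat: np.ndarray  # length m_prime + 1, index = duplication length
    n_hat: float
    residual: float  # ||C' q^ - rho~||^2 at the solution
    config: EstimationConfig
    L: int | None = None
    r_star: int | None = None
    d_suggestion: int | None = None
    warnings: tuple[str, ...] = ()

    @property
    def q0_hat(self) -> float:
        return float(self.q_hat[0])

    @property
    def low_copy_number(self) -> bool:
        return any("copy number" in w for w in self.warnings)


def dominant_lag(rho: AutocorrelationProfile) -> int:
    """r* = argmax_{r>=1} rho^r, smallest lag on ties."""
    if rho.m < 2:
        raise ValueError("profile must hold at least 2 lags")
    return int(np.argmax(rho.rho[1:]) + 1)


def select_window(rho: AutocorrelationProfile, d: int) -> tuple[int, int]:
    """Window rule m' = m'' = min(max(10 d, 5 r*), floor(L/2)).

    The max keeps the window large enough to cover plausible duplication
    lengths; the min keeps every needed lag within the computed profile
    (lags up to floor(L/2), each averaging at least L/2 position pairs).
    """
    r_star = dominant_lag(rho)
    cap = rho.m - 1  # profile computed to floor(L/2)
    w = min(max(10 * d, 5 * r_star), cap)
    return w, w


def build_design_matrix(
    rho: AutocorrelationProfile,
    m_prime: int,
    m_dprime: int,
    d: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design matrix C', right-hand side rho~, and column length labels.

    Without d: C' is m'' x (m'+1) with columns for lengths 0..m'.
    With d: the limit value 1/4 is substituted at lags not divisible by
    d, and only rows r and duplication columns i divisible by d are kept
    (plus the substitution column 0); the returned labels give the
    duplication length of each column after column 0.
    """
    max_lag = max(m_prime, m_dprime)
    if max_lag > rho.m - 1:
        raise ValueError(
            f"window ({m_prime},{m_dprime}) needs lags up to {max_lag}, "
            f"profile holds 0..{rho.m - 1}"
        )

    def value(lag: int) -> float:
        lag = abs(lag)
        if d is not None and lag % d != 0:
            return 0.25
        return rho.at(lag)

    rows = range(1, m_dprime + 1) if d is None else range(d, m_dprime + 1, d)
    cols = range(1, m_prime + 1) if d is None else range(d, m_prime + 1, d)
    rows = np.array(list(rows), dtype=int)
    cols = np.array(list(cols), dtype=int)
    if rows.size == 0 or cols.size == 0:
        raise ValueError("window too small: no rows/columns survive the d-reduction")
    C = np.empty((rows.size, cols.size + 1))
    rhs = np.empty(rows.size)
    for a, r in enumerate(rows):
        C[a, 0] = 2.0 / 3.0 + (r - 8.0 / 3.0) * value(r)
        for b, i in enumerate(cols):
            C[a, b + 1] = r * value(i - r)
        rhs[a] = r * value(r)
    return C, rhs, cols


def _solve_simplex_lsq(
    C: np.ndarray,
    b: np.ndarray,
    lengths: np.ndarray,
    enforce_length: bool,
    tol: float,
) -> np.ndarray:
    """min ||Cx-b||^2 (+ tiny ridge) s.t. sum x = 1, x >= 0[, a.x >= 1].

    SLSQP from the uniform start, then an exact KKT polish on the active
    set it identifies; deterministic given the inputs.
    """
    k = C.shape[1]
    a_len = np.concatenate([[0.0], lengths.astype(float)])

    H = C.T @ C + _RIDGE * np.eye(k)
    g = C.T @ b

    def fun(x):
        r = C @ x - b
        return float(r @ r + _RIDGE * x @ x)

    def jac(x):
        return 2.0 * (H @ x - g)

    cons = [{"type": "eq", "fun": lambda x: x.sum() - 1.0,
             "jac": lambda x: np.ones(k)}]
    if enforce_length:
        cons.append({"type": "ineq", "fun": lambda x: a_len @ x - 1.0,
                     "jac": lambda x: a_len})
    x0 = np.full(k, 1.0 / k)
    res = scipy.optimize.minimize(
        fun, x0, jac=jac, method="SLSQP", bounds=[(0.0, 1.0)] * k,
        constraints=cons, options={"ftol": 1e-14, "maxiter": 500},
    )
    x = np.clip(res.x, 0.0, None)
    s = x.sum()
    if s > 0:
        x = x / s

    x = _kkt_polish(H, g, a_len, enforce_length, x, fun, tol)
    return x


def _kkt_polish(H, g, a_len, enforce_length, x, fun, tol):
    """Exact equality-constrained solve on the active set found by SLSQP."""
    k = H.shape[0]
    active_zero = x < 1e-8
    eq_rows = [np.ones(k)]
    eq_rhs = [1.0]
    if enforce_length and a_len @ x < 1.0 + 1e-8:
        eq_rows.append(a_len)
        eq_rhs.append(1.0)
    for i in np.nonzero(active_zero)[0]:
        e = np.zeros(k)
        e[i] = 1.0
        eq_rows.append(e)
        eq_rhs.append(0.0)
    E = np.vstack(eq_rows)
    f = np.array(eq_rhs)
    ncon = E.shape[0]
    KKT = np.block([[2.0 * H, E.T], [E, np.zeros((ncon, ncon))]])
    rhs = np.concatenate([2.0 * g, f])
    try:
        sol = np.linalg.solve(KKT, rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(KKT, rhs, rcond=None)
    cand = sol[:k]
    feasible = (
        cand.min() >= -1e-9
        and abs(cand.sum() - 1.0) <= 1e-9
        and (not enforce_length or a_len @ cand >= 1.0 - 1e-9)
    )
    if feasible and fun(np.clip(cand, 0.0, None)) <= fun(x) + tol:
        cand = np.clip(cand, 0.0, None)
        return cand / cand.sum()
    return x


def estimate_q(
    rho: AutocorrelationProfile, config: EstimationConfig
) -> tuple[np.ndarray, float]:
    """Solve the constrained least-squares problem for q^.

    Returns (q_hat, residual): q_hat has length m_prime + 1 indexed by
    duplication length (entries at non-multiples of d are 0 when d is
    given); residual is the unregularized objective ||C' q^ - rho~||^2.
    """
    C, b, lengths = build_design_matrix(
        rho, config.m_prime, config.m_dprime, config.d
    )
    x = _solve_simplex_lsq(C, b, lengths, config.enforce_length_constraint,
                           config.tol)
    q_hat = np.zeros(config.m_prime + 1)
    q_hat[0] = x[0]
    q_hat[lengths] = x[1:]
    r = C @ x - b
    return q_hat, float(r @ r)


def estimate_n(q_hat: np.ndarray, L_final: int, L_seed: int) -> float:
    """Mutation-count estimate n^ = (L_final - L_seed) / sum_i i q^_i."""
    denom = float(np.arange(len(q_hat)) @ np.asarray(q_hat))
    if denom <= 0.0:
        raise ValueError(
            "expected length gain per mutation is zero (q^_0 = 1 with the "
            "length constraint disabled); n^ is undefined"
        )
    return (L_final - L_seed) / denom


def smtr(
    s: CircularSequence | str,
    d: int | None = None,
    seed_length: int | None = None,
    config: EstimationConfig | None = None,
    low_copy_estimator=None,
) -> EstimationResult:
    """Full SMTR pipeline: profile -> window -> design -> q^ -> n^.

    ``d`` is the pattern length if known (enables the reduced system and
    the length constraint); ``seed_length`` overrides the default
    assumption that the seed is one pattern long. ``low_copy_estimator``
    is an optional hook ``(s, d, result) -> EstimationResult`` applied
    when the copy number L/d is at most 3, where the asymptotic
    approximation is weakest.
    """
    if isinstance(s, str):
        s = CircularSequence(s)
    L = len(s)
    rho = circular_autocorrelation(s)
    r_star = dominant_lag(rho)
    if config is None:
        m_p, m_pp = select_window(rho, d if d is not None else 1)
        config = EstimationConfig(m_prime=m_p, m_dprime=m_pp, d=d)
    q_hat, residual = estimate_q(rho, config)

    notes: list[str] = []
    if d is not None and L / d <= 3:
        notes.append(
            f"copy number {L / d:.2f} <= 3: asymptotic approximation is "
            "unreliable for this sequence"
        )
    if config.enforce_length_constraint:
        lengths = np.arange(len(q_hat))
        if lengths @ q_hat < 1.0 + 1e-6:
            notes.append("length constraint active")

    L_seed = seed_length if seed_length is not None else (d if d is not None else 1)
    try:
        n_hat = estimate_n(q_hat, L, L_seed)
    except ValueError as exc:
        n_hat = float("nan")
        notes.append(str(exc))

    above = np.nonzero(rho.rho[1:] > 0.8)[0]
    d_suggestion = int(above[0] + 1) if above.size else None

    result = EstimationResult(
        q_hat=q_hat, n_hat=n_hat, residual=residual, config=config, L=L,
        r_star=r_star, d_suggestion=d_suggestion, warnings=tuple(notes),
    )
    if low_copy_estimator is not None and d is not None and L / d <= 3:
        result = low_copy_estimator(s, d, result)
    return result
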