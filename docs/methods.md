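# Methods

## Model

A tandem repeat is represented as a circular sequence over {A,C,G,T};
circularity removes boundary effects from the analysis, and observed
(linear) repeats are wrapped into circular form when their
autocorrelation is computed, at the cost of an O(1/copy-number) edge
bias at the junction. Evolution starts from a short seed and proceeds by
discrete mutation events. Given that an event occurs, it is a
substitution with probability q₀ (uniform position, uniform choice among
the three other bases — substitutions are unbiased, with no
transition/transversion distinction) or a tandem duplication of length ℓ
with probability q_ℓ (uniform template start; the copy is inserted
immediately after the template; a template longer than the current
sequence wraps around the circle). Insertions, deletions, and
heterogeneity-dependent duplication rates are outside the model. A
substitution may hit a previously mutated site: the model is memoryless.

## Limit theory

Let R^r count positions matching their r-th circular neighbour and
ρ = R/L. The expected one-event change of R is, exactly for
substitutions and exactly for duplications as well (see "Numerical
findings"),

- substitution: ΔR^r = −8/3·ρ^r + 2/3 (alphabet-size-4 constants),
- duplication of length ℓ: ΔR^r = r·ρ^{r−ℓ} − r·ρ^r + ℓ·ρ^r,

with negative lags read by the symmetry ρ^{−k} = ρ^k. Stochastic
approximation turns the resulting recursion, with step size 1/L_n, into
the linear ODE dρ/dt = Aρ. The rate matrix A is assembled entry-by-entry
from q (`theory.build_rate_matrix`); its row 0 vanishes because ρ⁰ ≡ 1.
The profile converges to Null(A):

- q₀ = 0: Null(A) = span of the lag-class indicators v₀ … v_{⌊d/2⌋},
  d = gcd of the duplication support. The repeat becomes approximately
  periodic with period d. Convergence is exponential in ODE time but the
  process only accumulates ODE time logarithmically (t(n) ≈ ln(1+n)/E[ℓ]),
  so observed convergence is polynomially slow in n: for lengths {4,6}
  the slowest relevant eigenvalue is ≈ −0.44, giving 1 − ρ² ~ n^(−0.088);
  at n = 3000 the ODE (and matching simulation) put ρ² near 0.59, and
  values above 0.95 would require astronomically many events. Tests
  therefore check monotone convergence toward 1 and agreement with the
  ODE value, not an arbitrary closeness to 1.
- q₀ > 0: Null(A) is one-dimensional; the unique limit with ρ⁰ = 1 is
  computed by the bordered linear solve (impose ρ⁰ = 1, solve rows
  1..m−1), which is deterministic — no eigen-iteration. Entries at lags
  not divisible by d equal 1/4 exactly.

Null-space dimensions are decided with a singular-value cutoff of 1e-10
relative to the largest singular value.

## Estimator

Rearranging Aρ∞ = 0 row-by-row yields C**q** = ρ̃ with
C_r0 = 2/3 + (r − 8/3)ρ^r, C_ri = r·ρ^{|i−r|}, ρ̃_r = r·ρ^r. The
|i−r| reading of the lag follows from the profile symmetry and is
validated algebraically against the rate-matrix rows. Truncating to m′
unknowns and m″ equations and replacing ρ∞ by the observed profile gives
the constrained least-squares problem on the probability simplex. When
the pattern length d is known, probabilities at non-multiples of d are
fixed to zero, 1/4 is substituted at off-period lags, and only
rows/columns at multiples of d are retained.

Window rule: m′ = m″ = min(max(10d, 5r*), ⌊L/2⌋), r* the smallest lag
maximizing ρ (first maximizer on ties — deterministic, favouring short
periods). The profile itself is computed only to lag ⌊L/2⌋ so that every
value averages at least L/2 position pairs. When d is unknown the
pipeline runs the full (unreduced) system with d_eff = 1 in the window
rule and reports, as a diagnostic only, the smallest lag with ρ > 0.8 as
a pattern-length suggestion.

Solver: the quadratic program (simplex constraint, nonnegativity,
optional expected-length constraint Σ(kd)q_{kd} ≥ 1) is solved by SLSQP
from the uniform start (ftol 1e-14), followed by an exact KKT solve on
the identified active set; feasibility and optimality are accepted at
1e-9. A fixed ridge of 1e-9 on ‖q‖² acts purely as a deterministic
tie-break: for degenerate fits — a perfect repeat makes every simplex
point with q₀ = 0 an exact solution — the solver then returns the
minimum-norm point of the optimal face, i.e. the near-uniform
duplication-length profile, rather than an arbitrary vertex. The ridge
perturbs well-posed solutions by far less than the 1e-6 recovery
tolerance used in tests.

The expected-length constraint is a practical prior (it guarantees
n̂ ≤ length growth) and defaults to on only when d is known, matching
its d-indexed statement. It can exclude the true model when d = 1
(a substitution-heavy model can add under one base per mutation), so
forward-inverse consistency is tested with the constraint off.

The mutation count n̂ divides the length growth by the expected length
added per mutation, Σ i·q̂ᵢ, with seed length taken equal to d (1 when d
is unknown), overridable when the true seed is known. For copy number
L/d ≤ 3 the asymptotic premise is weak: the result carries a structured
warning, and a `low_copy_estimator` hook allows plugging in a dedicated
short-sequence procedure without API change; no unspecified heuristic is
silently substituted.

## Synthetic data and the recovery study

The generator is the study's data source: pattern length d uniform on
1..10, seed of length d with i.i.d. uniform bases, q₀ uniform on
[0, 0.5], duplication mass spread over {d, 2d, …, 5d} by a symmetric
Dirichlet(1,…,1) draw. These defaults describe repeats formed by
polymerase slippage with duplication lengths that are whole multiples of
the pattern. What the generator does not emulate: indels, substitution
bias, GC-content effects, heterogeneity-dependent duplication rates, or
recombination-driven (typically minisatellite) repeats — so passing
tests demonstrate correct inference under the model, not robustness to
those real-data departures; on real catalogs the indel filter and the
unbiased-substitution assumption remain caveats.

The recovery study runs N = 100 replicates per grid point over
n ∈ {10, 50, 100, …, 500} with n_s = 5 sequences per replicate —
desk-scale sizes chosen so the whole study re-runs in minutes; per-
replicate estimates for the multi-sample condition are averaged over
estimates (q̂ vectors and n̂ values), never over autocorrelations. The
harness is fully deterministic given its generator. Error metrics are
the L2 distance ‖q̂ − q‖₂ (vectors zero-padded to a common length) and
NRMSE(n) = (1/n)·√(mean (n̂ᵢ − n)²).

## Catalog preprocessing

Records from a Tandem Repeats Finder table are dropped if they contain
N bases, have copy number below 2, or have nonzero indel percentage
(the reported copy number is used as-is, not recomputed). Overlap means
any interval intersection on the same chromosome; each overlap cluster
keeps one record — highest score, then longest, then earliest start — a
deterministic rule favouring the best-supported annotation. Coordinates
are 1-based inclusive throughout. Repeats are taken on the forward
strand; the autocorrelation is invariant under reverse complement
(asserted as a test), so no strand handling is needed.

## Numerical findings

Two questions the closed forms leave open were settled by enumeration:

1. The substitution drift −8/3·ρ^r + 2/3 is *exact* at every lag
   1 ≤ r ≤ L−1, including the boundary lag r = L/2: there the two match
   pairs affected by a substitution coincide, but each appears twice in
   the R-sum, so no boundary correction arises. Verified over all 4^L
   sequences for L ≤ 6.
2. The duplication expectation r·ρ^{r−ℓ} − r·ρ^r + ℓ·ρ^r is also exact
   (machine precision, lags reduced modulo L) for every ℓ and r tested;
   the O(1/L) remainder of the normalized recursion stems from dividing
   by the growing length, not from this conditional expectation.

## Known limitations

- Identifiability fails without substitutions (q₀ = 0): only the gcd of
  the duplication support is observable.
- Convergence to the limit profile is slow (logarithmic ODE time), so
  estimates from short histories are noisy; the error curves in the
  recovery study quantify this.
- Duplication mass can leak between a length and its multiples, which
  imprint similar profile signatures; q̂ recovers the mixture best when
  substitutions are common enough to break the degeneracy.
- No finite-sample confidence intervals are provided; the limit theory
  is asymptotic.
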