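# Methods

## Model and assumptions

The package models a closed cohort of `n0` individuals moving among `s`
mutually exclusive, exhaustive health states.  Assumptions:

* **Markov, time-invariant rates.** Each individual is a continuous-time
  Markov chain with constant transition intensities `c_kl ≥ 0` (units 1/year
  by default; units are metadata only and never converted implicitly).
  Self-rates are identically zero: a self-transition leaves the state
  configuration unchanged and would be unidentifiable, so generator
  diagonals are always derived as negative row sums, never user-supplied.
* **Independence and exchangeability.** Individuals transition
  independently; only the counts per state matter.  This is what makes the
  count process a Markov chain on the lattice of configurations with fixed
  total `n0` and gives the master equation a closed-form solution.
* **Closed cohort.** No entries, no births; totals are conserved exactly
  (deterministically by row-stochasticity, stochastically by integer
  bookkeeping).

The transition probability matrix over a duration `t` is the matrix
exponential `B(t) = exp(Qt)`, computed with scipy's scaling-and-squaring
`expm` (near machine precision for the norms occurring here; a truncated
series would not be).  `B(t)` is row-stochastic and satisfies the semigroup
property, both of which are asserted in property tests.

## The four routes and why they must agree

1. **Cohort simulation** (discrete time): `N(t+τ) = N(t) P_τ` with
   `P_τ = exp(Qτ)`, real-valued occupancies.
2. **Continuous-time cohort model**: `dN/dt = N Q`.  Because the system is
   linear with constant coefficients the exact solution `N0 exp(Qt)` is
   used directly; a numerical ODE integrator is deliberately *not* used
   here (it appears only inside the master-equation oracle), so the route
   has no step-size artifacts and agrees with route 1 at cycle boundaries
   through the semigroup identity `exp(Qτ)^n = exp(Qnτ)`.
3. **Analytic moments of the count process**: mean `n0 B_1i(t)`, variance
   `n0 B_1i(t)(1−B_1i(t))` for a degenerate start; the mean is identical to
   routes 1–2, which is the package's central demonstration.
4. **Monte Carlo**: microsimulation and Gillespie SSA sample the count
   process exactly; their empirical moments estimate the analytic ones.

## Master equation machinery

* **Lattice enumeration** is colexicographic over the `C(n0+s−1, s−1)`
  compositions of `n0`, with a configurable cap (default 2×10⁶
  configurations) and an explicit error directing callers to the analytic
  or Monte Carlo path when exceeded.  The exact lattice distribution is a
  verification-scale tool; the moment formulas are the production-scale
  tool.
* **Brute-force oracle.** The flux-balance right-hand side is assembled
  once as a sparse matrix and integrated with LSODA at rtol 1e-10 /
  atol 1e-12.  A stiff-capable method is required because rates in a single
  model can span orders of magnitude (0.001 vs 2 in the benchmark model);
  for lattices up to 2000 configurations the constant Jacobian is passed
  densely.  Solutions are clipped at zero and renormalized (drift is below
  1e-9).
* **Multinomial masses** are evaluated via log-gamma so that `n0 = 10000`
  does not overflow; configurations with a zero-probability category and a
  positive count get mass exactly zero.
* **Arbitrary initial conditions.** The law at time `t` is the mixture over
  initial configurations of the convolution of one multinomial per source
  state (the `n⁰_k` individuals starting in state k scatter with category
  probabilities `B_k·(t)`).  The convolution is performed on a dense
  `(n0+1)^s` count grid by iterating over source states — not by
  enumerating joint outcomes — which is exact and fast at
  verification scale.  The variance uses the law of total variance,
  `Var = E[conditional second moment] − mean²`; this form reproduces the
  degenerate-start formula exactly and matches the brute-force oracle,
  and the initial distribution (not the current-time law, which would be
  circular) is the mixing weight.

## Stochastic engines

* **Microsimulation** redistributes each state's occupants with one
  multinomial draw per state per cycle.  Individuals being exchangeable and
  independent, this is distributionally identical to simulating `n0`
  individual chains, and turns the 1000-replicate benchmark into a
  sub-second computation.
* **SSA (direct method)** draws exponential waiting times with the total
  propensity `Λ(n) = Σ c_kl n_k` and picks events proportional to their
  propensities, terminating at `t_max` or when `Λ = 0`.  Sampling a path at
  a query time uses the right-continuous convention: an event stamped
  exactly at the query time has already taken effect.
* **Seeding contract.** Replicate `r` of an ensemble with master seed `S`
  uses `numpy.random.default_rng(SeedSequence(S, spawn_key=(r,)))`.  This
  derivation is public: any replicate can be regenerated in isolation, and
  distinct replicates have independent streams.

## Agreement criterion for the Monte Carlo benchmark

The reference verification reports visual agreement of curves; the package
operationalizes it: per state×time cell, the empirical mean must lie within
`3·sqrt(V_i(t)/R)` of the analytic mean, and the empirical (unbiased)
variance must fall in the two-sided 99% chi-square interval
`[V·χ²_{0.005,R−1}/(R−1), V·χ²_{0.995,R−1}/(R−1)]`; a run passes when ≥95%
of cells pass.  Cells with analytic variance zero (e.g. `t = 0`) require
exact agreement.  The chi-square interval assumes approximate normality of
the counts, which holds at the benchmark scales (`n0·p` well above 10 for
the cells that matter); for cells with very small expected counts the
interval can undercover slightly, which is why the criterion is a 95% pass
fraction rather than per-cell certainty.

## Embedding

`generator_from_transition_matrix` uses the principal matrix logarithm
divided by the step.  A matrix with a non-positive real eigenvalue (e.g.
the period-2 flip) is rejected outright; off-diagonal entries of the
candidate logarithm in `[−1e-8, 0)` are treated as `logm` round-off and
clipped to zero, anything more negative is a hard "not embeddable" failure
reporting the offending entries.  The round trip `Q → exp(Qτ) → Q` is exact
to ~1e-13 for `‖Q‖τ ≤ 5`.

## Built-in benchmark and problem sizes

The shipped example is a 4-state progressive model (absorbing S4) with
rates `0.05, 0.01, 0.001, 0.1, 0.05, 2` per year, `n0 = 10000` starting in
S1, τ = 1 year, and 1000 Monte Carlo replicates.  The 50-cycle horizon is
a package choice (long enough for ~92% absorption); the exact-distribution
cross-checks run at `n0 = 10` (lattice size 286) and random 3-state models
at `n0 ≤ 6`, and the SSA benchmark at `n0 = 500` with 500 replicates —
sizes at which the brute-force oracle is exact to the integrator tolerance
and the whole verification runs in seconds.

## Synthetic fixtures and what passing shows

`random_model` draws off-diagonal rates i.i.d. exponential (mean
`rate_scale`, default 0.5/year, each channel present with probability 0.7),
which by construction always yields a valid generator.  These fixtures
exercise the algebraic invariants (semigroup, conservation, embedding,
oracle agreement) across model structures.  They do not emulate features of
real decision models — time-varying (e.g. age-specific) rates, tunnel
states, costs/utilities — so passing tests demonstrates internal
mathematical consistency of the implemented process, not fitness of the
time-invariant Markov assumption for any particular disease.

## Known limitations

* Time-invariant rates only; the piecewise approach to time-varying rates
  (re-initializing with the arbitrary-start formulas per interval) is not
  implemented.
* Exact lattice distributions are limited by the enumeration cap; beyond it
  only moments and Monte Carlo are available.
* No half-cycle correction, tau-leaping, system-size expansions, or
  cost/QALY accumulation.
* The embeddability check addresses the principal logarithm only; branch
  ambiguities of non-primary logarithms are out of scope.
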