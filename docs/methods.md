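# Methods

## Model

A metropolitan area is treated as a closed system of `N` zones with a
fixed total population `x̄ = Σᵢ xᵢ(t)`: residents relocate between zones,
but external migration and boundary growth are ignored.  Time is
discrete in years, matching the resolution at which relocation tables
are typically published.  The zone populations evolve as a Markov chain

```
X(t+1) = X(t) · P,
```

with `X` a row vector and `P` row-stochastic (populations are row
vectors throughout; stationary vectors are left eigenvectors).  `P` is
factored in mover–stayer form

```
P = (1 − ε) I + ε H,
```

where `ε ∈ [0, 1]` is the yearly relocation frequency (`τ = 1/ε` the
characteristic residence time) and `H` is the spatial kernel — the
row-stochastic matrix of destination probabilities conditional on
moving.  Kernels estimated from origin–destination flow tables have a
zero diagonal (`h_ij = T_ij / Σ_{k≠i} T_ik`, `h_ii = 0`); analytic toy
kernels are allowed a nonzero diagonal, and the convention is recorded
on the type.

Population heterogeneity in mobility is modelled as a mixture of
components `(α_k, ε_k, H_k)`, `Σ α_k = 1`, each evolving independently
under its own `P_k`.  When all components share one kernel, the
stationary state of the whole system is the stationary vector of `H`
scaled to `x̄`, independent of every `ε_k` and `α_k`, and each component
relaxes to `α_k · X_eq`.  This is what makes long-run structure
predictable from aggregate flow data alone, without knowing the
component memberships.

## Equilibrium and relaxation

`X_eq` is computed as the left unit-eigenvector of `P` (equivalently of
`H`) by dense eigendecomposition, clipped to nonnegative and scaled to
`x̄`; an independent power-iteration oracle cross-checks it in the test
suite.  Uniqueness is reported via the `is_unique` flag, which tests
irreducibility as primitivity of the lazy chain `(I + P)/2`.  The lazy
form is used because irreducible-but-periodic kernels (a two-zone swap,
a hub-and-spoke star) have a unique stationary vector yet no strictly
positive power; a strict-primitivity check (`is_primitive`) is also
exported and gates the relaxation diagnostics, where aperiodicity
genuinely matters.  Reducible kernels (absorbing destination blocks)
are flagged, never rejected: the computed vector is drawn from the
dominant eigenspace.

Relaxation is expressed through the driving force `U(t) = X(t) − X_eq`
and rate `Q(t) = X(t+1) − X(t)`, related by the discrete transport law
`Q = U · L` with transport matrix `L = P − I = −ε(I − H)` (both forms
are computed and must agree to 1e−12).  Near equilibrium, `‖U(t)‖`
decays exponentially with rate `log |λ₂(P)|`, where
`λ₂(P) = 1 − ε(1 − λ₂(H))` relates the kernel's and the model's second
eigenvalues (ordered by modulus; complex pairs are allowed and their
modulus is reported).  Diagnostics fit the tail slope of `log ‖U(t)‖`
by least squares over the last half of the trace (configurable), using
the Euclidean norm by default (L1 optional) and normalising by the
component mass `α_k x̄` so traces of different sizes are comparable.  A
trace whose driving force is below `1e−12 · x̄` across the window is
rejected as already at equilibrium.

## Two-component calibration

Window stayer shares `s₁` (one year) and `s₅` (five years) identify the
two frequencies at fixed mixing share `α` through

```
α(1−ε₁)   + (1−α)(1−ε₂)   = s₁
α(1−ε₁)⁵  + (1−α)(1−ε₂)⁵  = s₅ .
```

`α` is not identifiable from two window lengths and must be supplied
(0.9 by default).  Substituting `a = 1−ε₁` into the linear equation
leaves a quintic in `a`; the solver scans 10⁴ points of the exactly
feasible interval `a ∈ [max(0, (s₁−(1−α))/α), min(1, s₁/α)]` (both
survivals in [0, 1]) and refines every sign change by bisection to
1e−12.  Two root-finding corner cases are handled explicitly:

* roots at the interval endpoints (e.g. `s₅ = s₁` at `α = s₁`, solved by
  `ε₁ = 0, ε₂ = 1`), where no sign change is available;
* the tangent double root at the admissibility boundary `s₅ = s₁⁵`
  (both rates equal).  Since `f′(a) = 5α(a⁴ − b⁴)`, the only admissible
  tangency is `a = b = s₁`, so that single candidate is probed directly.

Roots are reported slow-component-first (`ε₁ ≤ ε₂`) as triples
`(ε₁, ε₂, α₁)`, where `α₁` is the slow component's share — the input
`α` or its complement, exploiting the exact `α ↔ 1−α` symmetry of the
system.  Every reported root satisfies both equations to 1e−10; an
admissible system with no root is a countable outcome
(`n_solutions = 0`), not an exception, since the zero/one/two-solution
landscape over `(α, s₅)` is itself an object of study
(`count_solutions`).

The calibrated stayer curve is the survival mixture
`α(1−ε₁)ᵗ + (1−α)(1−ε₂)ᵗ` at integer horizons; movers returning to
their origin within the window are deliberately excluded here, whereas
the matrix-power share `diag(Σ α_k P_k^t)` (used by `stayer_share` and
flow extrapolation) includes them, which is how census windows observe
residence.  Matrix powers are taken by repeated multiplication, not
eigendecomposition, to keep results bit-stable at the horizons involved
(t ≲ 50).

## Refractory (post-move immobility) model

The rival explanation — people simply do not move for `τ` years after a
relocation — is implemented as a discrete renewal chain over
age-since-last-move: hazard 0 for ages `< τ`, constant hazard `q`
otherwise.  The stationary age distribution is proportional to
survival, which lumps to `π(a<τ) = q/(1+τq)`, `π(≥τ) = 1/(1+τq)`; the
calibration `q = (1−s₁)/(1−τ(1−s₁))` makes the stationary one-year
stayer share equal `s₁` and is feasible iff `τ ≤ s₁/(1−s₁)`.  The
window stayer share is the stationary-age-weighted no-move probability,
computed by powers of the `(τ+1)`-state survival-only transition
matrix.  Because the refractory residents contribute no moves, the
eligible must move more often than `1−s₁`, pushing the five-year share
*below* `s₁⁵` — the opposite direction from the data, which is the
argument for genuine mobility heterogeneity.  An independent
agent-based Monte-Carlo simulator (`simulate_immobility_share`,
stationary initialisation, vectorised over 10⁶ agents) validates the
analytic chain to within Monte-Carlo error.

## Synthetic cities

The generators provide every fixture the tests need:

* **Linear city** — 99 zones on a line, centre at zone 50, destination
  weight `e^{∓β d_j}` with `β = 0.1` by default (`d_j` the zone-unit
  distance to the centre).  The origin-dependent factors cancel under
  row normalisation, so each kernel has identical rows equal to its own
  stationary vector; with the mover–stayer factor the second eigenvalue
  of `P` is exactly `1 − ε`, making this city a sharp spectral test
  case.  The printed periphery-seeking variant is normalised over
  destinations (the evident intent; a row-index normalisation would not
  be stochastic).
* **Random block kernels** — component 1's destinations confined to a
  zone block (default 26–74), component 2's to the complement, entries
  uniform(0,1) before row normalisation, deterministic under a mandatory
  seed.  These are the extreme heterogeneous-kernel case: stationary
  supports equal the positive-column sets.
* **Destination split** — factors an observed kernel `H` into
  `(H₁, H₂)` with `α H₁ + (1−α) H₂ = H` exactly (to 1e−12), component 1
  targeting a chosen zone set.  Rows are reassigned branch-wise
  depending on whether the row's in-set mass `a_i` is below or above
  `α`.

Zones are 1-based in specifications (matching "zone 50" language) and
0-based internally.

What the toys do not emulate: real kernels are sparse, distance-decayed
in two dimensions, and estimated from noisy counts; toy kernels are
dense, one-dimensional or random, and exact.  Passing tests therefore
demonstrate the correctness of the machinery and the robustness
properties (aggregate-kernel equilibrium error, spectral decay,
conservation), not goodness-of-fit to any real city.

## Numerical choices

* Row sums of stochastic matrices must be within 1e−9 of 1 at
  construction; they are renormalised exactly once there and never
  silently afterwards.  Consequently CSV round trips are bit-identical
  for exact-decimal inputs and for raw flow tables, and agree to 1e−15
  for kernels whose rows only sum to 1 up to rounding.
* Eigen tolerance 1e−8 on the unit eigenvalue; entries above 1e−15
  count as positive in primitivity checks.
* CSV numbers are written with `repr` (shortest round-trip form) and
  read with pandas' `round_trip` parser.
* Problem sizes in the test and acceptance runs: 99-zone cities,
  trajectories up to 10³ steps, 10⁶ Monte-Carlo agents, 10⁴-point
  calibration scans — all chosen as the smallest sizes at which the
  asymptotic claims (spectral slopes, stationarity, Monte-Carlo
  agreement) are comfortably resolved.

## Known limitations

* The relocation matrix is assumed constant in time; all long-run
  statements are conditional on that stability.
* `α` cannot be estimated from two window lengths; results are reported
  conditional on a supplied `α`, and the solution-count map documents
  where the choice matters.
* Equilibrium "detailed balance" (pairwise equal opposing flows) holds
  only for reversible chains; the package tests stationarity of the
  marginals, which is what the model actually implies.
* No geography: distances, thresholds and destination sets are supplied
  explicitly; no shapefiles or coordinates are handled.
* The spreading index sometimes used to summarise urban compactness is
  out of scope (its definition lives outside this model).
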