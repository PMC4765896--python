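# Methods

## Model and assumptions

The package models the adult-bee population of a single hive as one
continuous, nonnegative state variable `N(t)`, time in days. Two
demographic processes carry *component Allee effects* — density
dependence that is positive at low abundance:

* recruitment saturates, `λN/(θ+N)`: brood survive to adulthood only if
  enough workers feed and warm them, so per-capita recruitment
  `λ/(θ+N)` falls from the intercept `λ/θ` toward zero;
* per-capita mortality declines with crowd size,
  `αβ/(β+N) + μ`: cooperative foraging, thermoregulation and defence
  drop it from `μ+α` in a tiny hive to the asymptote `μ`.

The net rate `m(N) = λN/(θ+N) − (αβ/(β+N) + μ)N` defines the ODE; a
discrete recast `N_{t+1} = N_t + m(N_t)` with a one-day step is provided
for exploratory use. Deliberately out of scope: caste/stage structure,
seasonality, swarming as an explicit event, stochastic (demographic or
environmental) noise, and multi-hive coupling. One state variable is
enough for the questions the package answers — existence and loss of a
critical hive size.

Zero is treated as absorbing (`m(0) = 0`), and the state is a real
number throughout; bee *counts* appear only if a caller rounds output.

## Equilibria and case logic

`m(N) = 0` factors as `N(aN² + bN + c) / ((θ+N)(β+N))` with `a = −μ`,
`b = λ−αβ−μθ−μβ`, `c = β(λ−αθ−μθ)`, so the positive equilibria are
quadratic roots, computed with the cancellation-safe (citardauq)
pairing so that parameter sets spanning many orders of magnitude do not
lose precision. Because `a < 0`, the textbook "minus" root is the
*larger* one; the package therefore defines `n_crit = min` and
`n_stable = max` of the positive roots, which is what the dynamics
require (lower unstable, upper stable). A root is accepted only if
`|m(root)| ≤ 1e-8·λ` — scaling by λ makes the tolerance unit-free.

Case classification uses the per-capita intercept geometry:
`CASE_1` iff `λ/θ > α+μ`; `CASE_2` iff `λ/θ < α+μ`, `λ/θ > μ`, `b > 0`
and `b² − 4ac > 0`; `CASE_3` otherwise. Exact boundary equalities are
measure-zero and fall to `CASE_3`, with one exception: a vanishing
discriminant with positive repeated root is the fold itself, classified
`CASE_2` with the equilibrium labelled `degenerate` (the package does
not assert semistability there). Stability elsewhere is the sign of the
closed-form slope `m′(N) = λθ/(θ+N)² − αβ²/(β+N)² − μ`; central
differences serve only as a test oracle.

The collapse index is implemented as `b² / (4μβ(μθ+αθ−λ))`. The factor
4 in the denominator is required for the advertised equivalence
`index > 1 ⟺ b² − 4ac > 0` (when the denominator is positive); on the
`c = 0` boundary the index is undefined and the package returns NaN
with a `boundary_c_zero` flag on the report rather than raising.

## Numerical choices

* **Integration**: `solve_ivp` RK45, `rtol 1e-8`, `atol 1e-6` bees, with
  an automatic LSODA retry on failure; output on a uniform grid
  (default 1 day) independent of internal steps. Values are clipped at
  zero on output only — with `m(0)=0` clipping removes nothing but
  roundoff.
* **Map negativity**: large daily rates make the one-day map overshoot
  below zero; the default policy raises (hiding the regime behind a
  silent clamp would mask exactly the pathology the discrete form is
  prone to). `clamp` and `allow` policies record events instead.
* **Attractor detection**: a trajectory is `collapsed` below 1 bee (one
  individual is the natural floor of the count interpretation) and
  `converged_upper` within 1% of `n_stable`; shorter or intermediate
  runs are `undetermined`.
* **Fold location**: bisection (Brent) on `b² − 4ac`, a polynomial in
  each parameter, rather than on the index's ratio form with its
  `c = 0` pole; refined to ~1e-12 relative, then the index's equality
  with 1 is verified post hoc. Sweeps hold all other parameters fixed.
* **Potential**: `u(N) = (αβ−λ)N + (μ/2)N² − αβ²·ln(β+N) + λθ·ln(θ+N)`,
  natural logarithms, normalised so `u(0) = 0`. The potential is defined
  only up to a constant; the normalisation makes the barrier measured
  from extinction directly readable and plots comparable. Basin *width*
  is operationalised as `n_stable − n_crit` and *depth* as
  `u(n_crit) − u(n_stable)` — these are this package's definitions of
  the otherwise qualitative basin language. Metrics come from the
  closed-form equilibria; grid extrema are cross-checks only.

## Fixtures: what they emulate and what they do not

No empirical parameter estimates ship with the package; the bundled
fixtures are chosen for biologically plausible magnitudes — a queen
laying up to ~2000 eggs/day (`λ`), baseline adult mortality ~2%/day
(`μ`, a ~50-day worker lifespan), cooperation scales of 5–16 thousand
bees (`β`, `θ`), and a six-fold mortality excess in a tiny hive (`α`).
`case2_default` yields a critical size of ~1.3k bees and an upper stable
size of ~48k — a commercial package of ~11k bees sits comfortably above
threshold, matching beekeeping practice. `case1` raises `λ` to 3000
(weak Allee effect; `λ` rather than a lower `θ` so the per-capita curve
keeps its low-density rise), `case3` has `μ = 0.2`, and `near_fold`
(`μ = 0.036`, fold at `μ* ≈ 0.0372`) shows a basin about to vanish.

Passing tests therefore demonstrate the *mathematical* structure —
threshold, fold, basin erosion — under these conditions, not calibrated
predictions for real colonies: real hives have seasonality, swarming,
stochastic shocks and age structure that the model deliberately omits.
Figure output is likewise structure-faithful (curve counts, crossings,
monotone trends), not a numeric reproduction of any published plot.

## Verification strategy and problem sizes

Every closed form is checked against an independent numerical route:
quadratic roots against sign-change bracketing of the per-capita rate
(which has at most one interior extremum, so two brackets suffice) over
200 random parameter sets log-uniform across four decades per
parameter; the potential's gradient against central differences and its
barrier against adaptive quadrature of `−m`; the asocial closed form
against adaptive integration; fold locations against dense discriminant
scans. The separatrix property uses 50 initial sizes log-spaced over
`(n_crit/100, 2·n_stable)` excluding a ±1% band around the threshold,
integrated to 6000 days — long relative to the slowest time scale near
the threshold (`1/m′(n_crit) ≈ 93` days) so every trajectory commits to
an attractor. The small-rate map check scales `λ, α, μ` by 1/4 (a
uniform per-capita slowdown that leaves the equilibria untouched); the
large-rate check scales them by 100.

## Known limitations

* The discrete map is a diagnostic, not a recommended solver; it is
  accurate only when daily per-capita rates are ≪ 1.
* Exact boundary parameter sets (fold, `c = 0`) are handled, but
  floating-point arithmetic rarely lands on them; callers probing
  boundaries should test small neighbourhoods instead.
* `viability_region` evaluates the classification pointwise on the
  grid; it does not refine the boundary between grid nodes.
* No stochastic exit-time analysis is built on the potential; barrier
  depth is a geometric resilience proxy, not a first-passage rate.
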