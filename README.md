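# hive-allee

Population dynamics of a honey-bee hive with **component Allee effects**:
a single-state-variable model for theoretical ecologists, bee researchers,
and modellers studying colony collapse, tipping points, and ecological
resilience.

## The model

Let `N` be the number of adult bees (continuous, time in days). In an
**asocial** baseline, recruitment is constant and mortality proportional:

    dN/dt = λ − μN,      N(t) = λ/μ + (N₀ − λ/μ) e^(−μt)

so every hive, however small, climbs to the equilibrium `λ/μ`. Real hives
are not like that: brood rearing needs adult workers, and cooperative
foraging and defence suppress mortality. The **social** model builds both
mechanisms in:

    dN/dt = λN/(θ + N) − (αβ/(β + N) + μ) N

* `λ` — maximum recruitment rate (bees/day), capped by the queen's laying;
* `θ` — hive size at half-maximal recruitment (bees);
* `α` — excess per-capita mortality of a tiny hive (1/day);
* `β` — hive size at which that excess has decayed halfway (bees);
* `μ` — baseline per-capita mortality of a large hive (1/day).

The per-capita growth rate `λ/(θ+N) − αβ/(β+N) − μ` *rises* with hive
size at low `N` — the hallmark of an Allee effect. Equilibria are `N = 0`
plus the roots of `aN² + bN + c = 0` with `a = −μ`,
`b = λ − αβ − μθ − μβ`, `c = β(λ − αθ − μθ)`. Three regimes:

1. **Case 1** (`λ/θ > α+μ`): one positive stable equilibrium; weak Allee
   effect, every hive viable.
2. **Case 2** (strong Allee effect): a lower *unstable critical size*
   `N̄₁` and an upper *stable size* `N̄₂`; hives below `N̄₁` collapse
   deterministically, hives above it recover to `N̄₂`.
3. **Case 3**: mortality dominates everywhere; all hives collapse.

The dimensionless **collapse index**
`b² / (4μβ(μθ + αθ − λ))` exceeds 1 exactly when the two positive
equilibria exist; degrading any parameter (λ down; θ, β, α, μ up) drives
it toward 1, where the equilibria merge in a saddle-node (fold)
bifurcation and vanish. Resilience is read off the potential `u(N)` with
`u′ = −dN/dt`: the depth `u(N̄₁) − u(N̄₂)` and width `N̄₂ − N̄₁` of the
basin of attraction of the upper state.

## Worked example

```python
from hive_allee import fixtures, solve_equilibria, discriminant_quantity, potential_profile

p = fixtures()["case2_default"]     # λ=2000, θ=16000, α=0.12, β=5000, μ=0.02
rep = solve_equilibria(p)
print(rep.case.value)               # CASE_2
print(round(rep.n_crit, 1))         # 1256.7  — critical hive size (bees)
print(round(rep.n_stable, 1))       # 47743.3 — upper stable size (bees)
print(round(discriminant_quantity(p), 3))   # 10.004 — well above the fold at 1
prof = potential_profile(p)
print(round(prof.basin_width, 1))   # 46486.6 — basin width (bees)
```

A hive of ~1257 bees or fewer is doomed under these conditions; one above
that grows to ~47.7k. Raising baseline mortality pushes the system to the
fold at `μ* ≈ 0.0372`/day, where both equilibria merge at ~8321 bees:

```sh
$ hive-allee fold --fixture case2_default --param mu --bracket 0.02 0.2
{
  "param": "mu",
  "fold_value": 0.03719179727085233,
  "fold_state": 8321.354475079335,
  ...
}
```

Other subcommands: `simulate` (ODE or daily map trajectories, CSV/plot),
`equilibria` (JSON/CSV report), `potential` (profile + basin metrics),
`bifurcate` (branch diagram over a parameter sweep), `figures` (render
the seven standard diagnostic figures), `fixtures`. Parameters come from
a flat YAML file (`--config`), a bundled fixture (`--fixture`), or
individual flags.

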