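# Model and methods

## The model

`colonysim` simulates a clonal yeast colony as a stochastic cellular
automaton coupled to a diffusing scalar field. The lattice is a
`grid_size × grid_size` square grid (default 250); one grid length
represents 50 µm, so a site holds a "cell block" of roughly 100 cells.
A site is empty, dark (gluconeogenic, resource-producing) or light
(PPP-state, resource-consuming); blocks are never mixed, never die, and
never move. One time step represents 12 min; the default run of 750
steps covers 150 h of colony development.

Assumptions worth stating explicitly:

- Amino acids (the dark blocks' growth substrate) are ambient and
  saturating everywhere; only the shared resource is modeled as a field.
- The resource field is external: internal reserves do not diffuse and
  are private to a block.
- The colony is two-dimensional; vertical structure of a real colony is
  not represented.
- All stochasticity (initial light placement, per-block sweep order,
  switching, division, tie-breaks) flows from a single seeded
  generator, so a run is a pure function of its parameters.

## Per-step dynamics

Each step sweeps the blocks occupied at the start of the step in a fresh
random permutation (avoiding raster-scan bias; daughters born during a
sweep first act the following step), then performs exactly one diffusion
update.

Dark block at `(x, y)`:

1. If `u(x,y) ≥ S`: switch to light with probability `p`; a block that
   switches does nothing else this step. (In the `linear_switching`
   rule set the probability is `min(m·u, 1)` instead of the constant
   `p`; the printed formula with `max` would be identically 1 and is
   read as a typo for `min`.)
2. Otherwise add `R` units to `u(x,y)`.
3. Take up `C` units of ambient amino acids into the internal reserve.
4. With reserve ≥ 1.0, divide with probability `g_d` (see below).

Light block at `(x, y)`:

1. If `u(x,y) ≥ C`: consume the maintenance ration `C` and internalize
   the remainder up to the block's storage bound of 1.0 unit (the
   amount needed to divide); surplus stays external and keeps
   diffusing.
2. If `u(x,y) < C` and switch-back is enabled: revert to dark, keeping
   both reserves, and stop for this step.
3. With resource reserve ≥ 1.0, divide with probability `g_l`.

Division targets the empty von Neumann neighbor with the most occupied
von Neumann neighbors of its own (ties broken uniformly at random);
without an empty neighbor the division silently aborts. The daughter
inherits the mother's state, and both internal reserves are halved
between mother and daughter, so division neither creates nor destroys
internal mass.

### The bounded-uptake rule

The single most consequential design decision is that a light block's
appetite is bounded: maintenance `C` per step plus top-up to the 1.0-unit
division requirement. With unbounded perpetual uptake, lights sitting at
the dark/light interface siphon the entire production of the dark
interior indefinitely; the resource halo around the colony then never
reaches the switching threshold, no light blocks ever appear at the rim,
the colony barely expands, and the total resource rises monotonically —
none of the behaviors this model exists to produce. With the bounded
store, sated interior lights let resource flow past them, the halo
builds, rim blocks cross the threshold ~150–250 steps after the first
interior switches, and the peripheral light boom follows. The
maintenance ration is what later turns the boom into net consumption:
total external resource peaks around steps 450–550 (day ~3.5–4.5) and
declines thereafter, and starved lights revert to dark, maintaining the
mixed dark/light mesh of the colony interior.

### Switch-back

Reversion of starved light blocks to the dark state is controlled by
`switchback_enabled` (default on). It is immediate (no rate parameter)
and keeps both reserves; a reverted block may switch again later, and a
re-switched block with a full store can divide at once. The
`no_threshold` and `linear_switching` rule sets disable reversion. With
reversion on, all initially seeded light blocks revert at step 1, since
the resource field starts at zero everywhere.

## Parameters

| name | meaning | units | default |
|---|---|---|---|
| `g_dark` | dark division probability | 1/step | 0.01 |
| `g_light` | light division probability | 1/step | 0.04 |
| `switch_threshold` (S) | resource level gating switching | units | 3.0 |
| `production` (R) | resource added per dark block | units/step | 0.07 |
| `consumption` (C) | per-block metabolite intake | units/step | 0.05 |
| `division_reserve` | internal reserve needed to divide | units | 1.0 |
| `switch_prob` (p) | switch chance when gated on | 1/step | 0.5 |
| `diffusion` (D) | resource diffusion constant | L²/step | 0.24 |
| `grid_size` | lattice side | sites | 250 |
| `init_radius` | seeded disk radius | grid lengths | 20 |
| `init_light_fraction` | seeded light share | — | 0.02 |
| `n_steps` | run length | steps | 750 |
| `dt_minutes`, `dx_micron` | real-time/-space scale | min, µm | 12, 50 |
| `linear_slope` (m) | slope for linear switching | 1/units | 0.5 |
| `reverse_production` (R′) | light→amino production | units/step | 0.07 |

Division rates reflect the observed fast growth of light cells relative
to dark; `R` and `C` are 7% and 5% of the division requirement; `D` sits
just below the FTCS stability limit. The seeded light share defaults to
2%, inside the 1–5% range the initial-state description allows; the
exact published value is not stated, and with switch-back on the choice
is immaterial (all initial lights revert at step 1). `m` has no
published value; 0.5 makes the linear switching probability saturate at
`u = 2`, comparable to the wild-type threshold scale.

## Initial state

Every site within `init_radius` (closed Euclidean disk) of the grid
center is occupied — 1257 sites at radius 20. `round(fraction ×
occupied)` of them, chosen uniformly without replacement, start light.
All internal reserves and the resource field start at zero; a
consequence is that the earliest dark division is at step 20 (when
`C·t` first reaches 1.0) and the earliest dark→light switch at step 44:
the threshold check precedes each step's production, so the first check
that can see `u ≥ S` is the one after `⌈S/R⌉ = 43` production steps.

## Diffusion numerics

The field update is the explicit FTCS scheme with unit time step and
grid length, `u ← u + D·(u_N + u_S + u_E + u_W − 4u)`, applied
simultaneously at all sites. Edges are no-flux (reflecting), so
diffusion alone conserves the total to float accumulation error
(≤ 1e−9 per step in the tests). The von Neumann bound `D ≤ ΔL²/4ΔT =
0.25` is enforced at validation and again in the update; above it the
scheme oscillates and goes negative.

## Analysis conventions

- **Hill fit**: time is the dose variable; `t ≤ 0` points are dropped
  (the Hill form vanishes there) and the signal is normalized to its
  maximum. Multi-start least squares over starting exponents
  {0.5, 1, 2, 4, 8}, with the fit constrained to an identifiable
  region — normalized plateau ≤ 2, half-rise time ≤ 10× the observed
  window, exponent ≤ 200. Without these bounds an unsaturated rise
  degenerates into a power law with `K` and `Fmax` diverging together.
  Failure returns `converged=False` rather than garbage.
- **Linear fit**: ordinary least squares; `r² = 1 − RSS/TSS`; a
  zero-variance response is reported as slope 0 with `r² = 0` by
  convention and flagged.
- **Perimeter emergence**: the first stored snapshot (after step 0) in
  which some light block has an empty von Neumann neighbor — the same
  adjacency the division rule uses. Step 0 is excluded because its
  light placement is random rather than emergent.
- **Radial metrics** are measured from the seeding center, not the
  centroid, so they are stable under asymmetric growth; profile bins
  are equal-width annuli spanning [0, max occupied radius] and
  partition the occupied blocks exactly.
- **Resource peak**: argmax of the per-step total external resource,
  first index on ties.

## Synthetic data

The generators produce what the analysis stage assumes and nothing
more: Hill-shaped or linear reporter rises with additive Gaussian noise
truncated at zero (fluorescence is non-negative), with the generating
parameters recorded alongside, and deterministic toy snapshots
(uniform disk, dark core/light rim, checkerboard). They emulate the
statistical shape of reporter time courses — not microscope optics,
spatial fluorescence distributions, background autofluorescence, or
photobleaching. Passing round-trip tests therefore shows the fitting
machinery is correct and calibrated, not that real colony fluorescence
follows a Hill law.

## Problem sizes

The test suite exercises full-size runs (250 × 250 grid, 750 steps,
three seeds — a few seconds each) for the phenotype assertions, and
small grids (side ≤ 41) for mechanics-level tests. The acceptance
script runs three full wild-type simulations and a 64 × 64 stability
probe. The switch-waiting-time distribution check uses 200 single-block
runs of 70 steps.

## Known limitations

- The light-block count of a default run rises in two phases: an
  interior switching wave at steps ~44–50 (these blocks are
  division-constrained) and the cooperative perimeter boom after step
  ~200. A single Hill curve fitted to the whole course averages the
  two and yields an exponent near 0.85–1.05 rather than the clearly
  cooperative value the late phase alone would suggest; the fitted
  exponent also depends on truncating the run mid-boom at step 750.
- The post-peak decline of total external resource is real but
  gradual at the default horizon: ~20–40% below peak at step 750,
  halving at roughly step 1100, because the far halo beyond the
  advancing light front is consumed only as the front reaches it.
- Blocks never die and never mix; the model cannot represent partial
  or graded metabolic states within a site.
- The reverse-sharing amino-acid field is bookkeeping: it is seeded
  saturating, receives the light blocks' contribution, and does not
  diffuse or limit growth.
- Real-unit conversion of `D` (0.24 L²/T × (50 µm)²/12 min ≈ 8.3 ×
  10⁻¹³ m²/s) is order-of-magnitude only; the lattice is not a
  quantitative transport model of agar.
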