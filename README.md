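# colonysim

A stochastic lattice model of metabolic division of labor in clonal
budding-yeast colonies, with the analyses that quantify how the colony's
two cell states organize in space and time.

## The science

Mature yeast colonies on low-glucose agar spontaneously segregate into
two metabolic states: optically dense **dark** cells running
gluconeogenesis, and rarer **light** cells running a
pentose-phosphate-pathway (PPP) program. The dark cells secrete a
diffusible resource (trehalose, in the biology); where its local
concentration crosses a threshold, dark cells switch to the fast-growing
light state, which is sustained by consuming that resource. The result is
a self-organized cross-feeding economy: a producing dark interior, a
resource halo, and rapidly expanding light outcrops at the colony rim.

`colonysim` implements this as a coarse-grained agent model. The colony
lives on a 250 × 250 grid (one site = a 50 µm "cell block" of ~100
cells); each site is empty or holds an all-dark or all-light block. Per
time step (12 min of real time):

- a dark block at local resource `u ≥ S` switches to light with
  probability `p`; while still dark it adds `R` units of resource at its
  site, takes up `C` units of the ambient amino acids, and with internal
  reserve ≥ 1.0 divides with probability `g_d` into the most crowded
  empty von Neumann neighbor;
- a light block pays a maintenance ration `C` from the local resource
  and internalizes the remainder up to the 1.0 units it needs to divide
  (probability `g_l`); if less than `C` is available it reverts to dark;
- the external resource field then diffuses by one explicit FTCS
  (forward-time, central-space) update, stable for `D ≤ 0.25` in grid
  units.

Wild-type constants: `g_d = 0.01`, `g_l = 0.04`, `S = 3.0`, `R = 0.07`,
`C = 0.05`, `p = 0.5`, `D = 0.24`, 750 steps (150 h). Five published
control rule sets are built in (`no_sharing`, `no_switching`,
`reverse_sharing`, `no_threshold`, `linear_switching`).

The analysis layer computes composition time courses, switch timing,
perimeter emergence, radial composition profiles, colony extent, and
cooperativity: the rise of a signal F(t) is fitted with the Hill form

    F(t) = Fmax · tⁿ / (Kⁿ + tⁿ)

by multi-start nonlinear least squares; the exponent *n* measures how
switch-like the rise is (n ≈ 1 graded, n ≫ 1 cooperative). A synthetic
data module generates Hill-shaped and linear reporter courses with known
ground truth, plus toy colony snapshots, so every analysis is testable
against parameters you chose.

## Worked example

```
$ colonysim simulate --seed 1 --steps 750 --out wt_run
[colonysim] simulating variant=wildtype seed=1 steps=750 grid=250
[colonysim] done: final n_dark=1308 n_light=1957; wrote wt_run

$ colonysim analyze --traj wt_run
metric,value
first_switch_step,44
perimeter_emergence_step,230
resource_peak_step,544
final_occupied,3265
final_max_radius,36.6742416417845
final_diameter,73.348483283569
real_time_hours,150.0
hill_n_light_counts,0.8556159381638955
hill_K_light_counts,1144.1897909277184
```

Reading the numbers: the colony seeds as a radius-20 disk of 1257 blocks
(98% dark). For 43 steps the resource builds at `R` per step, so the
first dark→light switch can fire at step 44 — and does. Light blocks
emerge at the colony perimeter at step 230 and expand the colony to
radius ~37 (diameter ~73 grid lengths ≈ 3.7 mm) by step 750. The total
external resource peaks at step 544 (~day 4.5 of the 6-day run) and
declines as the booming light population consumes it. The Hill exponent
fitted to the light-block count is ~0.86 here: the count rises in two
phases (an early interior switching wave, then the late perimeter boom),
which a single Hill curve smooths into a near-graded rise.

The same is available in Python:

```python
import colonysim as cs

traj = cs.run(cs.default_params().replace(seed=1))
print(cs.first_switch_step(traj), cs.resource_peak_step(traj))
profile = cs.radial_profile(traj.final_grid, n_bins=8)  # rim vs core
```

`colonysim synth` writes reporter curves with recorded truth, and
`colonysim hillfit` recovers their parameters:

```
$ colonysim synth --family hill --seed 3 --n 4 --k 3 --noise-sd 0.02 --out series.csv
$ colonysim hillfit --input series.csv
{"n": 3.88, "K": 3.10, "Fmax": 1.03, "rss": 0.0073, "converged": true}
```

`colonysim render` turns any stored snapshot into a PNG, one pixel per
grid site.

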