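# prairieopt

Cost–benefit optimization of grassland restoration site selection.

`prairieopt` is a spatially explicit planning tool for deciding **where to
restore habitat** when budgets are limited. It was built around the problem
of restoring North American prairie (shortgrass, mixed-grass and tallgrass
communities on land that is currently cropland or pasture), but every layer
is generic: a historical habitat map, a current land-cover map, a per-pixel
land-value surface, and range maps for a set of indicator species.

## The model

For each species *j*, extinction risk follows a power-law species–area
relationship (SAR) between the current habitat area *A_c* and the original
(historical) area *A_O*:

```
r0_j = 1 − (A_c / A_O)^z
```

with *z* the exponent controlling how risk scales with habitat loss
(default 0.25; sensitivity range 0.1–0.4). Restoring one pixel of area
*A_xi* inside the species' historical range and preferred habitat type
lowers the risk to `r1_j = 1 − ((A_c + A_xi)/A_O)^z`, so the per-pixel
benefit is

```
b_ij = c_ij × w_ij × (r0_j − r1_j)
```

where `c_ij ∈ [0,1]` is an optional climate-suitability weight (from a
species distribution model) and `w_ij` a dispersal weight: pixels within
the species' dispersal distance of its current range always weigh 1, and
pixels beyond it weigh 1, 0.5 or 0 in the *no-dispersal*, *intermediate*
and *natural-dispersal* scenarios respectively. Pixel benefits are summed
over species, `B_xi = Σ_j w_j b_ij`, and sites are selected by integer
linear programming:

```
max Σ_i (B_xi / C_xi) x_i
s.t. Σ_i A_xi x_i ≤ T_A          (area cap per run)
     Σ_{i∈G_a} A_xi x_i ≥ H_A    (minimum per habitat type a)
```

with `C_xi` the pixel acquisition cost (USD/ha × pixel area). Because
*z* < 1 every restored pixel shrinks the benefit of the next one
(diminishing returns), the optimization runs in iterations — by default
three runs of 10% of the available pixels each, reaching a 30% restoration
target with at least 20% of every habitat type restored — updating each
species' *A_c* after every iteration. The solve is exact (HiGHS via
`scipy.optimize.milp`, zero optimality gap) with a deterministic tie-break
(cheaper pixels first, then lower pixel index).

## Worked example

`prairieopt.synthetic.generate_worked_example()` returns a fixed 6×6
landscape (1 km cells, three habitat bands, costs rising from $1000/ha in
the northwest corner by $100 per cell in reading order, 32 restorable
pixels) with two species that each retain part of their historical range:

```python
import prairieopt as po
from prairieopt.synthetic import generate_worked_example

bundle, profiles = generate_worked_example()
available = po.compute_available_area(bundle.habitat, bundle.landcover)
weights = po.dispersal_weight_surface(profiles[0], po.DispersalMode.NONE, bundle.grid)
surfaces = [po.species_benefit_surface(p, p.initial_state(), available, weights)
            for p in profiles]
total = po.aggregate_benefit(surfaces)
cfg = po.ScenarioConfig(per_iteration_fraction=6/32, target_fraction=18/32,
                        min_habitat_fraction_total=0.0)
problem = po.build_problem(total, bundle.cost, available, cfg)
selection = po.solve_ilp(problem)
```

The optimal 6-pixel selection is `(0,0) (0,1) (0,2) (0,5) (1,4) (1,5)` at a
total cost of **$890,000** (the sum of those pixels' USD/ha costs × 100 ha),
with summed benefit/cost objective 1.2698×10⁻⁶. Adding a binding minimum of
two habitat-2 pixels shifts the selection to
`(0,0) (0,1) (0,2) (0,5) (1,2) (1,4)` ($860,000) — the optimizer swaps the
most expensive low-ratio pixel for the best habitat-2 candidate. Both
selections match exhaustive enumeration over all subsets.

A full scenario run from the shell:

```
prairieopt synth --seed 11 --rows 48 --cols 48 --out demo
prairieopt run --config demo/config.yaml --out demo/run_none --scenario no_dispersal
```

prints

```
run_none: 240 pixels, total $30,504,340, avg $1380/ha
```

and writes `scenario_summary.json` (cost and area-by-habitat accounting),
`scenario_species_risk.csv` (per-species risk before/after across
z ∈ {0.1, 0.25, 0.4}), `selection.asc` (iteration labels per pixel) and a
run manifest. In that run every synthetic species starts at
`A_c/A_O = 0.5`, i.e. risk `1 − 2^−0.25 ≈ 0.159104`; three iterations of
restoration reduce it by 0.85–3.16 percentage points depending on how much
eligible area each species gains.

The five standard scenario presets are `no_dispersal`, `intermediate`,
`natural`, `maxent_ssp370` and `rf_ssp370` (the last two multiply benefits
by per-species suitability surfaces). `prairieopt sweep` runs the z
sensitivity sweep and `prairieopt compare` tabulates runs and writes the
all-scenario intersection mask.

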