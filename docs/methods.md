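# Methods

## Model

The planning problem is: given a landscape partitioned into equal-area
pixels, decide which pixels to restore so that the summed per-pixel
benefit/cost ratio is maximal under an area budget and per-habitat-type
floor constraints.

**Benefit.** Species-level benefit is the reduction in SAR extinction risk
from adding one pixel of habitat. With current area `A_c`, original area
`A_O` (both planar polygon areas of the range maps, in km², computed in
the projected equal-area CRS) and exponent `z`:

    r(A) = 1 − (A / A_O)^z
    Δr   = r(A_c) − r(A_c + A_xi)

`Δr` is constant across candidate pixels within one optimization
iteration (every pixel adds the same `A_xi`), so a species' benefit
surface is its eligibility mask — historical range ∩ preferred habitat
classes ∩ available (restorable) area — times `Δr`, times two optional
weights:

* *climate suitability* `c ∈ [0,1]`, an externally supplied surface (an
  SDM output); values outside [0,1] by more than 1e-6 are errors,
  smaller excursions are clamped;
* *dispersal weight* `w`: 1 inside the current range buffered by the
  species' dispersal distance, and 1 / 0.5 / 0 beyond it in the
  no-dispersal / intermediate / natural modes. The buffer is built once
  from the original current range and held fixed across iterations;
  stepping-stone buffer growth is deliberately not modeled.

Assumptions inherited from the SAR framing: restored pixels eventually
become habitat (long-term risk, not near-term); risk depends on total
area only, not configuration; species respond independently (benefits
add across species, optionally with per-species weights).

**Cost.** Land value in USD/ha per pixel (input may be ln USD/ha, the
convention of parcel-level land-value datasets; the exponential
transform is applied on load). Pixel cost is USD/ha × pixel area in ha.
Cost enters the objective as a ratio denominator; an optional budget
mode instead maximizes benefit subject to a total-cost cap.

**Selection.** With uniform pixel areas the two constraints reduce to
integer pixel counts: at most `floor(f · N)` pixels per run (`f` = 0.10
by default, `N` = all available pixels) and at least
`ceil((F/m) · |G_a|)` pixels of habitat `a` per run (`F` = cumulative
floor, default 0.20; `m` = number of iterations, default 3 — the
per-run coefficient 0.20/3 ≈ 0.067). Ceiling rounding on the floors
guarantees the cumulative minimum after `m` runs. The per-run cap and
floors are computed from the *full* available set, so they are constant
across iterations while the candidate pool shrinks by the pixels
already selected (restoration is permanent).

**Iteration.** After each run, every selected pixel inside a species'
historical range and preferred habitat increments that species' `A_c`
by one pixel area (km²), including — by default — pixels beyond the
dispersal buffer in natural mode, on the view that habitat exists
regardless of colonization speed; a config switch
(`count_outside_buffer_in_ac`) excludes them. Benefit surfaces are then
rebuilt, so later runs see strictly smaller `Δr` (diminishing returns,
`z < 1`).

## Solver

The objective is literally the *sum of per-pixel ratios* `Σ B_i/C_i x_i`
— a linear objective — not aggregate benefit over aggregate cost.
Readers expecting the aggregate ratio should note the distinction; the
sum-of-ratios form is what keeps the problem an ILP.

The ILP is solved through HiGHS (`scipy.optimize.milp`) at zero
optimality gap. Two structural facts are exploited:

1. **Total unimodularity.** The default constraint matrix (one
   cardinality cap row plus lower-bound rows over a partition of the
   pixels) is totally unimodular, so the LP relaxation's simplex
   vertices are exactly binary. The solver therefore runs on the
   relaxation; integrality of the returned vertex is *verified* (1e-9,
   never rounded) and any fractional vertex triggers a full
   branch-and-bound solve. The budget mode adds a fractional-coefficient
   row that breaks TU and always uses the binary solve.
2. **Canonical tie-break.** Among equal-objective optima the returned
   selection is the canonical one: per habitat the `k_a` best pixels,
   then the best remaining positive-ratio pixels up to the cap, ordered
   by ratio descending, cost ascending, pixel index ascending. An
   exchange argument shows this greedy construction is exactly optimal
   for the cap+partition system; its objective is cross-checked against
   the solver's optimum at 1e-9 relative. This makes output
   deterministic under ties (e.g. all-zero benefit problems return the
   cheapest feasible selection).

Objective coefficients are normalized to unit magnitude before solving:
realistic benefit/cost ratios are ~1e-7, below the solver's working
tolerances, and scaling leaves the argmax unchanged.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `z` | 0.25 | — | SAR exponent; sweep {0.1, 0.25, 0.4} |
| `target_fraction` | 0.30 | — | share of available pixels restored in total |
| `per_iteration_fraction` | 0.10 | — | share per run; × iterations must equal target |
| `min_habitat_fraction_total` | 0.20 | — | cumulative per-habitat floor (0 / 0.10 / 0.20 variants) |
| `n_iterations` | 3 | — | 30 × 0.01 gives the same target with finer steps |
| `dispersal_mode` | none | — | none / intermediate / natural |
| `restorable_landcover_codes` | {81, 82} | — | cropland + pasture land-cover classes |
| `cell_size` | 960 | m | pixel = 92.16 ha; 480 m (23.04 ha) also exercised |
| `cost_transform_order` | exp-then-coarsen | — | see below |
| `weight` (per species) | 1 | — | optional prioritization weight `w_j` |

## Numerical choices

* **Rounding.** Area cap: `floor`; habitat floors: `ceil` (guarantees
  cumulative minima). Display costs round to the nearest $10 with
  round-half-to-even; internal accounting is full float64.
* **Coarsening.** Continuous layers aggregate by the mean of non-nodata
  fine cells, categorical by the modal code with ties broken toward the
  lowest code; trailing partial blocks aggregate over the cells that
  exist. Whether the cost layer is exponentiated before or after
  aggregation is a config switch (`cost_transform_order`); the default
  exponentiates first, i.e. averages dollars rather than log-dollars.
* **Rasterization** uses the cell-center rule (a cell belongs to a
  polygon iff its center is strictly inside). Buffers are planar
  Euclidean with 32 segments per quadrant.
* **Degenerate inputs.** `A_c > A_O` (possible with independently
  sourced range maps) clamps risk to 0 with a warning. Nodata in any
  layer removes the pixel from the analyzable set for the whole bundle.
  An empty selection yields zero-cost summaries with a warning rather
  than an error. A habitat whose remaining candidates cannot meet its
  floor raises an infeasibility error naming the habitat and iteration.
* **Units.** SAR areas are km² throughout the species module; hectares
  appear only in the cost accounting. Conversions happen at module
  boundaries only.

## Synthetic data

`SyntheticSpec` defaults describe the study conditions the tool targets:
a 100×100 grid of 960 m cells; three prairie community classes in
longitudinal bands (a nearest-seed-point tessellation whose seed points
take their band's class, giving wiggly band edges — mirroring the
west-to-east shortgrass/mixed/tallgrass gradient; a fully random mosaic
mode is also available); ~35% of cells in restorable cropland/pasture
(smoothed-noise threshold at the exact quantile); a lognormal,
spatially autocorrelated land-value surface stored in ln USD/ha with
mean ln(2500) and sd 0.5 (Gaussian-filtered white noise, standardized
then rescaled); five species whose historical ranges are unions of
random disks biased to their preferred band, current ranges eroded to
half the historical area (negative buffer, bisection on the erosion
distance), and dispersal distances of 3–30 km spanning sedentary to
wide-ranging taxa; smooth [0,1] suitability fields. All randomness
derives from one integer seed through `numpy.random.SeedSequence`
spawning; identical seeds give bit-identical bundles. Any species whose
eligibility mask comes out empty is regenerated from a fresh sub-seed
up to ten times, then errors.

What the generator does *not* emulate: correlation between land value
and species geography (prices are independent noise), parcel shapes,
real dispersal kernels, or any statistical realism of Great Plains land
prices beyond lognormal autocorrelated structure. Two consequences for
interpreting the tests: passing structural tests says nothing about
absolute risk levels on real landscapes, and the *direction* of the
natural-dispersal cost premium is bundle-specific — the premium arises
when dispersal buffers exclude cheap eligible land, which on synthetic
bundles depends on where the random cost field happens to sit relative
to the ranges. The fixed-seed property test documents the direction on
its stated conditions; the acceptance script averages the premium over
three bundles.

The worked example (6×6, two species, integer costs) is fully
hard-coded and documented cell-by-cell in its docstring; its optimal
selections are verified against exhaustive enumeration in the test
suite.

## Problem sizes

Tests and the acceptance script run the full pipeline at up to 200×200
cells (≈14,000 candidate pixels, 3- and 30-iteration runs), solver
exactness at N ≤ 15 against exhaustive enumeration (100 instances) and
N ≤ 5,000 against the greedy oracle (100 instances). These sizes were
chosen as the smallest at which every structural claim (cap and floor
exactness, support orderings, composition stability across iteration
counts) is non-trivially exercised.

## Known limitations

* The sum-of-ratios objective is not the aggregate benefit/cost ratio;
  scenarios with very heterogeneous costs can rank differently under
  the two readings.
* `A_c` updates credit whole pixels to every species whose historical
  range and preferred habitat contain them; partial overlap at range
  edges is resolved by the cell-center rule, so very small ranges on
  coarse grids are noisy.
* Species interactions, connectivity, spatial clustering preferences
  and restoration feasibility/management costs are out of scope (the
  cost layer is acquisition value only).
* Geographic-CRS inputs are rejected, not reprojected; co-registration
  is the caller's responsibility.
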