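"""Exact site selection by integer linear programming.

Each optimization run maximizes the summed per-pixel benefit/cost ratio

    max sum_i (B_i / C_i) x_i ,   x_i in {0, 1}

subject to an area cap (at most T_A restored per run) and a minimum
restored area per habitat type (H_A).  Because every pixel has the same
area, both constraints reduce to exact integer pixel counts.  The solver
is HiGHS through scipy.optimize.milp with a zero optimality gap.

Diminishing returns are handled by running the optimization in
iterations: after each solve, newly selected pixels are added to each
species' current habitat area A_c and the benefit surfaces are rebuilt,
so later iterations see strictly smaller per-pixel benefits.

The objective is literally the sum of ratios (a linear objective), not
total benefit divided by total cost; readers expecting the aggregate
ratio should note the distinction.  An optional budget mode moves cost
out of the objective into a constraint (max sum B_i x_i subject to
sum C_i x_i <= budget).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .benefit import (
    AvailableArea,
    DispersalMode,
    TotalBenefitSurface,
    aggregate_benefit,
    compute_available_area,
    dispersal_weight_surface,
    species_benefit_surface,
)
from .geodata import (
    CategoricalSurface,
    ContinuousSurface,
    Grid,
    GridAlignmentError,
    LandscapeBundle,
    coarsen,
    exp_transform_cost,
    pixel_area_ha,
    pixel_area_km2,
    rasterize_range,
)
from .species import SpeciesProfile, SpeciesState

logger = logging.getLogger(__name__)


class InfeasibleProblemError(ValueError):
    """Raised when the constraint system admits no selection."""


@dataclass
class ScenarioConfig:
    """One scenario run: dispersal mode, climate use, SAR exponent, constraints.

    ``target_fraction`` of the available pixels is restored in total,
    split evenly over ``n_iterations`` runs of ``per_iteration_fraction``
    each.  ``min_habitat_fraction_total`` is the cumulative minimum share
    of each habitat type to restore (the per-iteration share is this
    divided by ``n_iterations``; a 20% floor over three iterations gives
    the 0.0667-per-run coefficient).
    """

    dispersal_mode: DispersalMode = DispersalMode.NONE
    climate_scenario: str | None = None
    z: float = 0.25
    target_fraction: float = 0.30
    per_iteration_fraction: float = 0.10
    min_habitat_fraction_total: float = 0.20
    n_iterations: int = 3
    random_seed: int = 0
    resolution_factor: int = 1
    restorable_landcover_codes: frozenset[int] = frozenset({81, 82})
    #: averaged-cost transform order when coarsening: exponentiate the
    #: ln-USD/ha layer before (default) or after aggregation
    cost_transform_order: str = "exp_then_coarsen"
    #: whether a restored eligible pixel beyond the dispersal buffer still
    #: counts toward A_c (habitat exists regardless of colonization speed)
    count_outside_buffer_in_ac: bool = True
    #: optional budget mode: maximize benefit subject to total cost <= cap
    budget_cap_usd: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.dispersal_mode, str):
            self.dispersal_mode = DispersalMode(self.dispersal_mode)
        for name in ("target_fraction", "per_iteration_fraction", "min_habitat_fraction_total"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if abs(self.n_iterations * self.per_iteration_fraction - self.target_fraction) > 1e-9:
            raise ValueError(
                "n_iterations * per_iteration_fraction must equal target_fraction "
                f"({self.n_iterations} * {self.per_iteration_fraction} != {self.target_fraction})"
            )
        if self.resolution_factor < 1:
            raise ValueError("resolution_factor must be >= 1")
        if self.cost_transform_order not in ("exp_then_coarsen", "coarsen_then_exp"):
            raise ValueError(f"unknown cost_transform_order {self.cost_transform_order!r}")

    @property
    def per_iteration_habitat_fraction(self) -> float:
        return self.min_habitat_fraction_total / self.n_iterations


@dataclass
class OptimizationProblem:
    """Flattened single-run selection problem over candidate pixels."""

    benefit: np.ndarray  # B_i, >= 0
    cost: np.ndarray  # USD per pixel, > 0
    habitat_code: np.ndarray  # habitat class per pixel
    pixel_area_ha: float
    max_pixels: int  # T_A expressed in pixels
    min_pixels_per_habitat: dict[int, int]  # H_A(a) in pixels
    flat_indices: np.ndarray | None = None  # position in grid.ravel()
    grid: Grid | None = None
    budget_cap_usd: float | None = None

    def __post_init__(self) -> None:
        n = len(self.benefit)
        if not (len(self.cost) == len(self.habitat_code) == n):
            raise ValueError("problem vectors must have equal length")
        if n and (np.any(self.cost <= 0) or np.any(self.benefit < 0)):
            raise ValueError("costs must be positive and benefits non-negative")
        needed = sum(self.min_pixels_per_habitat.values())
        if needed > self.max_pixels:
            raise InfeasibleProblemError(
                f"habitat minima require {needed} pixels but the area cap is "
                f"{self.max_pixels} pixels"
            )

    @property
    def n(self) -> int:
        return len(self.benefit)

    @property
    def ratio(self) -> np.ndarray:
        return self.benefit / self.cost


@dataclass
class Selection:
    """Result of one or more solves: chosen pixels with iteration labels."""

    chosen: np.ndarray  # bool over problem pixels
    iteration_label: np.ndarray  # int, 0 where unchosen
    flat_indices: np.ndarray | None = None
    grid: Grid | None = None

    @property
    def count(self) -> int:
        return int(self.chosen.sum())

    def label_raster(self) -> CategoricalSurface:
        """Grid raster of iteration labels (0 = unselected)."""
        if self.flat_indices is None or self.grid is None:
            raise ValueError("selection lacks grid placement information")
        labels = np.zeros(self.grid.n_rows * self.grid.n_cols, dtype=np.int64)
        labels[self.flat_indices] = self.iteration_label
        return CategoricalSurface(
            grid=replace(self.grid, nodata_code=-1), codes=labels.reshape(self.grid.shape)
        )


def build_problem(
    total_benefit: TotalBenefitSurface,
    cost: ContinuousSurface,
    available: AvailableArea,
    config: ScenarioConfig,
    candidate_mask: np.ndarray | None = None,
    n_total: int | None = None,
    habitat_counts: dict[int, int] | None = None,
) -> OptimizationProblem:
    """Flatten surfaces into a single-run selection problem.

    ``candidate_mask`` restricts candidates (e.g. to still-unselected
    pixels in later iterations); ``n_total`` and ``habitat_counts`` pin
    the cap and minima to the full available set so the per-iteration
    T_A = floor(f * N) and H_A(a) = ceil(f_a * |G_a|) stay constant
    across iterations.  Pixels with nodata cost are excluded entirely.
    """
    grid = available.grid
    if total_benefit.surface.grid != grid or cost.grid != grid:
        raise GridAlignmentError(
            "benefit, cost and available-area surfaces must share one grid"
        )
    base_mask = available.mask & cost.valid_mask & ~np.isnan(total_benefit.surface.values)
    if candidate_mask is not None:
        mask = base_mask & candidate_mask
    else:
        mask = base_mask
    if n_total is None:
        n_total = int(base_mask.sum())
    if n_total == 0:
        raise InfeasibleProblemError("no analyzable pixels are available for restoration")
    if habitat_counts is None:
        codes_all = available.surface.codes[base_mask]
        habitat_counts = {int(c): int((codes_all == c).sum()) for c in np.unique(codes_all)}

    flat = np.flatnonzero(mask.ravel())
    benefit = total_benefit.surface.values.ravel()[flat]
    cost_per_pixel = cost.values.ravel()[flat] * pixel_area_ha(grid)
    habitat = available.surface.codes.ravel()[flat]

    max_pixels = math.floor(config.per_iteration_fraction * n_total)
    frac_a = config.per_iteration_habitat_fraction
    minima: dict[int, int] = {}
    if frac_a > 0:
        for code, count in habitat_counts.items():
            need = math.ceil(frac_a * count)
            have = int((habitat == code).sum())
            if need > have:
                raise InfeasibleProblemError(
                    f"habitat {code}: minimum of {need} pixels exceeds the {have} "
                    "candidate pixels remaining"
                )
            minima[code] = need
    return OptimizationProblem(
        benefit=benefit,
        cost=cost_per_pixel,
        habitat_code=habitat,
        pixel_area_ha=pixel_area_ha(grid),
        max_pixels=max_pixels,
        min_pixels_per_habitat=minima,
        flat_indices=flat,
        grid=grid,
        budget_cap_usd=config.budget_cap_usd,
    )


def _milp_exact(c: np.ndarray, constraints: list, relax: bool = False) -> np.ndarray:
    """Binary solve at zero optimality gap.

    With ``relax=True`` the LP relaxation is solved instead: for the
    cap+partition-minima system the constraint matrix is totally
    unimodular with integer bounds, so every simplex vertex is exactly
    binary and the relaxation IS the integer optimum (much faster than
    branch and bound).  Integrality of the result is verified, never
    rounded; any fractional vertex triggers a full integer solve.
    """
    n = len(c)
    res = milp(
        c=c,
        constraints=constraints,
        integrality=np.zeros(n) if relax else np.ones(n),
        bounds=Bounds(0, 1),
        options={"mip_rel_gap": 0.0},
    )
    if res.status != 0 or res.x is None:
        raise InfeasibleProblemError(f"ILP solve failed: {res.message}")
    if relax and np.any(np.abs(res.x - np.round(res.x)) > 1e-9):
        logger.warning("fractional LP vertex on a TU system; re-solving as integer")
        return _milp_exact(c, constraints, relax=False)
    return res.x > 0.5


def _canonical_optimum(problem: OptimizationProblem, ratio: np.ndarray) -> np.ndarray:
    """Deterministic optimal selection for the cap+partition-minima problem.

    The constraint system (one cardinality cap plus lower bounds over a
    partition of the pixels) is totally unimodular, so an exchange
    argument shows this sorted greedy is exactly optimal: take the best
    k_a pixels of each habitat, then fill the remaining cap with the
    best positive-ratio pixels anywhere.  "Best" orders by ratio
    descending, then cost ascending, then pixel index — which is the
    documented tie-break.
    """
    n = problem.n
    order = np.lexsort((np.arange(n), problem.cost, -ratio))
    chosen = np.zeros(n, dtype=bool)
    for code, k in problem.min_pixels_per_habitat.items():
        in_habitat = order[problem.habitat_code[order] == code]
        chosen[in_habitat[:k]] = True
    remaining = problem.max_pixels - int(chosen.sum())
    if remaining > 0:
        fill = order[~chosen[order] & (ratio[order] > 0)][:remaining]
        chosen[fill] = True
    return chosen


def solve_ilp(problem: OptimizationProblem) -> Selection:
    """Solve the selection ILP to proven optimality.

    The MILP (HiGHS, zero optimality gap) establishes the optimal
    objective; the returned selection is the canonical optimum with the
    deterministic tie-break (prefer cheaper pixels, then lower index),
    cross-checked against the solver's value.  The objective is
    normalized to unit magnitude before solving — benefit/cost ratios
    can be ~1e-7, below the solver's working tolerances — which leaves
    the argmax unchanged.  In budget mode (cost as a constraint instead
    of in the objective) the solver's selection is returned directly.
    """
    n = problem.n
    if n == 0:
        return Selection(
            chosen=np.zeros(0, dtype=bool),
            iteration_label=np.zeros(0, dtype=np.int64),
            flat_indices=problem.flat_indices,
            grid=problem.grid,
        )
    if problem.budget_cap_usd is not None:
        objective = problem.benefit.astype(np.float64)
    else:
        objective = problem.ratio
    base = float(np.abs(objective).max())
    scaled = objective / base if base > 0 else objective

    constraints = [LinearConstraint(np.ones((1, n)), -np.inf, problem.max_pixels)]
    for code, k in problem.min_pixels_per_habitat.items():
        row = (problem.habitat_code == code).astype(float)[None, :]
        constraints.append(LinearConstraint(row, k, np.inf))
    if problem.budget_cap_usd is not None:
        constraints.append(
            LinearConstraint(problem.cost[None, :], -np.inf, problem.budget_cap_usd)
        )

    x = _milp_exact(-scaled, constraints, relax=problem.budget_cap_usd is None)
    if problem.budget_cap_usd is None:
        canonical = _canonical_optimum(problem, objective)
        v_solver = float(scaled[x].sum())
        v_canonical = float(scaled[canonical].sum())
        if v_canonical >= v_solver - 1e-9 * max(1.0, abs(v_solver)):
            x = canonical
        else:  # pragma: no cover - defensive: canonical construction is exact
            logger.warning(
                "canonical selection suboptimal (%.3e < %.3e); returning solver output",
                v_canonical,
                v_solver,
            )
    return Selection(
        chosen=x,
        iteration_label=x.astype(np.int64),
        flat_indices=problem.flat_indices,
        grid=problem.grid,
    )


def greedy_reference(problem: OptimizationProblem) -> Selection:
    """Test oracle: top-k pixels by benefit/cost ratio, index-order ties.

    Only valid for uniform pixel areas with no habitat minima, where the
    cardinality-capped selection is exactly solved by greedy ranking.
    """
    if problem.min_pixels_per_habitat:
        raise ValueError("greedy reference does not support habitat minima")
    order = np.argsort(-problem.ratio, kind="stable")
    chosen = np.zeros(problem.n, dtype=bool)
    chosen[order[: problem.max_pixels]] = True
    return Selection(
        chosen=chosen,
        iteration_label=chosen.astype(np.int64),
        flat_indices=problem.flat_indices,
        grid=problem.grid,
    )


# ---------------------------------------------------------------------------
# Iterative scenario loop
# ---------------------------------------------------------------------------


def _prepare_layers(
    bundle: LandscapeBundle, config: ScenarioConfig
) -> tuple[LandscapeBundle, ContinuousSurface]:
    """Resolution coarsening and the ln -> USD cost transform."""
    habitat, landcover, cost = bundle.habitat, bundle.landcover, bundle.cost
    suitability = dict(bundle.suitability)
    cost_is_ln = cost.units.lower().startswith("ln")
    f = config.resolution_factor
    if f > 1:
        habitat = coarsen(habitat, f)
        landcover = coarsen(landcover, f)
        suitability = {k: coarsen(v, f) for k, v in suitability.items()}
        if cost_is_ln and config.cost_transform_order == "exp_then_coarsen":
            cost = coarsen(exp_transform_cost(cost), f)
        elif cost_is_ln:
            cost = exp_transform_cost(coarsen(cost, f))
        else:
            cost = coarsen(cost, f)
    elif cost_is_ln:
        cost = exp_transform_cost(cost)
    new_bundle = LandscapeBundle(
        habitat=habitat, landcover=landcover, cost=cost, suitability=suitability
    )
    return new_bundle, cost


def run_iterative_scenario(
    bundle: LandscapeBundle,
    profiles: list[SpeciesProfile],
    config: ScenarioConfig,
):
    """Run the full diminishing-returns scenario loop.

    Each iteration rebuilds every species' benefit surface from its
    current SAR state, solves the ILP over still-unselected pixels, and
    credits newly restored pixels to each species whose historical range
    and preferred habitat contain them.  Returns the labelled
    :class:`Selection` and a :class:`~prairieopt.report.ScenarioReport`.
    """
    from .report import build_scenario_report  # deferred: report depends on this module

    bundle, cost = _prepare_layers(bundle, config)
    grid = bundle.grid
    available = compute_available_area(
        bundle.habitat, bundle.landcover, set(config.restorable_landcover_codes)
    )
    base_mask = available.mask & cost.valid_mask
    n_total = int(base_mask.sum())
    if n_total == 0:
        raise InfeasibleProblemError("available area is empty")
    codes_all = available.surface.codes[base_mask]
    habitat_counts = {int(c): int((codes_all == c).sum()) for c in np.unique(codes_all)}

    # static per-species structures: dispersal weights (buffer built once
    # from the original current range), eligibility and A_c-credit masks
    weights = {
        p.name: dispersal_weight_surface(p, config.dispersal_mode, grid) for p in profiles
    }
    suitability: dict[str, ContinuousSurface | None] = {}
    for p in profiles:
        suitability[p.name] = (
            bundle.suitability.get(p.name) if config.climate_scenario else None
        )
    credit_masks: dict[str, np.ndarray] = {}
    for p in profiles:
        historical = rasterize_range(p.historical_range, grid).codes == 1
        preferred = np.isin(available.surface.codes, list(p.preferred_habitat_codes))
        credit = historical & preferred & base_mask
        if config.dispersal_mode is DispersalMode.NATURAL and not config.count_outside_buffer_in_ac:
            credit &= weights[p.name].values >= 1.0
        credit_masks[p.name] = credit

    states = {p.name: p.initial_state() for p in profiles}
    states_before = {
        name: SpeciesState(s.area_current, s.area_original) for name, s in states.items()
    }
    labels = np.zeros(grid.n_rows * grid.n_cols, dtype=np.int64)
    px_km2 = pixel_area_km2(grid)

    for it in range(1, config.n_iterations + 1):
        surfaces = [
            species_benefit_surface(
                p,
                states[p.name],
                available,
                weights[p.name],
                suitability[p.name],
            )
            for p in profiles
        ]
        total = aggregate_benefit(surfaces, {p.name: p.weight for p in profiles})
        unselected = (labels == 0).reshape(grid.shape)
        try:
            problem = build_problem(
                total,
                cost,
                available,
                config,
                candidate_mask=unselected,
                n_total=n_total,
                habitat_counts=habitat_counts,
            )
            sel = solve_ilp(problem)
        except InfeasibleProblemError as exc:
            raise InfeasibleProblemError(f"iteration {it}: {exc}") from exc
        chosen_flat = problem.flat_indices[sel.chosen]
        labels[chosen_flat] = it
        newly = np.zeros(labels.shape, dtype=bool)
        newly[chosen_flat] = True
        newly = newly.reshape(grid.shape)
        for p in profiles:
            count = int((newly & credit_masks[p.name]).sum())
            states[p.name].add_restored(count * px_km2)
        logger.info(
            "iteration %d: selected %d pixels (cap %d)", it, len(chosen_flat), problem.max_pixels
        )

    all_flat = np.flatnonzero(base_mask.ravel())
    selection = Selection(
        chosen=labels[all_flat] > 0,
        iteration_label=labels[all_flat],
        flat_indices=all_flat,
        grid=grid,
    )
    report = build_scenario_report(
        selection=selection,
        cost=cost,
        available=available,
        profiles=profiles,
        states_before=states_before,
        states_after=states,
        config=config,
    )
    return selection, report
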