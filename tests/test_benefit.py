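"""Benefit surfaces: eligibility, dispersal weighting, aggregation."""

import numpy as np
import pytest
from shapely.geometry import box

from prairieopt.benefit import (
    DispersalMode,
    aggregate_benefit,
    compute_available_area,
    dispersal_weight_surface,
    species_benefit_surface,
)
from prairieopt.geodata import (
    CategoricalSurface,
    ContinuousSurface,
    Grid,
    GridAlignmentError,
    RangeGeometry,
    pixel_area_km2,
)
from prairieopt.species import SpeciesProfile, risk_reduction

ND = -9999


def grid4():
    return Grid(n_rows=4, n_cols=4, origin_x=0, origin_y=0, cell_size=1000.0)


def profile(grid, preferred={1}, dispersal=1.0, current=None, historical=None):
    width = grid.n_cols * grid.cell_size
    height = grid.n_rows * grid.cell_size
    return SpeciesProfile(
        name="sp",
        preferred_habitat_codes=preferred,
        dispersal_km=dispersal,
        current_range=RangeGeometry(current or box(0, 0, width / 2, height), "current"),
        historical_range=RangeGeometry(historical or box(-1, -1, width + 1, height + 1), "historical"),
    )


class TestAvailableArea:
    def test_all_restorable_keeps_habitat_map(self):
        g = grid4()
        habitat = CategoricalSurface(grid=g, codes=np.tile([1, 1, 2, 3], (4, 1)).astype(np.int64))
        landcover = CategoricalSurface(grid=g, codes=np.full((4, 4), 81, dtype=np.int64))
        out = compute_available_area(habitat, landcover)
        assert np.array_equal(out.surface.codes, habitat.codes)

    def test_nothing_restorable_is_empty_with_warning(self, caplog):
        g = grid4()
        habitat = CategoricalSurface(grid=g, codes=np.ones((4, 4), dtype=np.int64))
        landcover = CategoricalSurface(grid=g, codes=np.full((4, 4), 71, dtype=np.int64))
        with caplog.at_level("WARNING"):
            out = compute_available_area(habitat, landcover)
        assert not out.mask.any()
        assert any("no restorable" in r.message for r in caplog.records)

    def test_hand_enumerated_mask_intersection(self):
        g = grid4()
        habitat = CategoricalSurface(
            grid=g,
            codes=np.array(
                [[1, 1, 2, 2], [1, ND, 2, 3], [3, 3, 2, 1], [3, 1, 1, 2]], dtype=np.int64
            ),
        )
        lc = np.full((4, 4), 71, dtype=np.int64)
        cropland = [(0, 0), (0, 2), (1, 1), (1, 3), (2, 0), (3, 3)]
        for r, c in cropland:
            lc[r, c] = 81 if (r + c) % 2 == 0 else 82
        landcover = CategoricalSurface(grid=g, codes=lc)
        out = compute_available_area(habitat, landcover)
        # (1,1) is cropland but habitat-nodata: 5 cells survive
        expected = {(0, 0): 1, (0, 2): 2, (1, 3): 3, (2, 0): 3, (3, 3): 2}
        assert int(out.mask.sum()) == 5
        for (r, c), code in expected.items():
            assert out.surface.codes[r, c] == code
        assert out.surface.codes[1, 1] == ND

    def test_grid_mismatch_rejected(self):
        g = grid4()
        other = Grid(n_rows=4, n_cols=4, origin_x=10, origin_y=0, cell_size=1000.0)
        habitat = CategoricalSurface(grid=g, codes=np.ones((4, 4), dtype=np.int64))
        landcover = CategoricalSurface(grid=other, codes=np.full((4, 4), 81, dtype=np.int64))
        with pytest.raises(GridAlignmentError):
            compute_available_area(habitat, landcover)


class TestDispersalWeights:
    def test_mode_none_is_uniform_one(self):
        g = grid4()
        w = dispersal_weight_surface(profile(g), DispersalMode.NONE, g)
        assert np.all(w.values == 1.0)

    @pytest.mark.parametrize(
        "mode,outside", [(DispersalMode.INTERMEDIATE, 0.5), (DispersalMode.NATURAL, 0.0)]
    )
    def test_outside_buffer_weight(self, mode, outside):
        g = grid4()
        # current range = west half; buffer 1 km reaches column 2 centers exactly? no:
        # col 2 centers at x=2500, range edge 2000, buffer edge 3000 -> inside
        p = profile(g, dispersal=1.0, current=box(0, 0, 2000, 4000))
        w = dispersal_weight_surface(p, mode, g)
        assert np.all(w.values[:, :3] == 1.0)
        assert np.all(w.values[:, 3] == outside)


class TestSpeciesBenefit:
    def _setup(self):
        g = grid4()
        habitat = CategoricalSurface(
            grid=g, codes=np.tile([1, 1, 2, 2], (4, 1)).astype(np.int64)
        )
        landcover = CategoricalSurface(grid=g, codes=np.full((4, 4), 82, dtype=np.int64))
        available = compute_available_area(habitat, landcover)
        return g, available

    def test_zero_outside_historical_range(self):
        g, available = self._setup()
        p = profile(g, preferred={1, 2}, historical=box(0, 0, 2000, 4000),
                    current=box(0, 0, 1000, 2000))  # west half only, half retained
        w = dispersal_weight_surface(p, DispersalMode.NONE, g)
        out = species_benefit_surface(p, p.initial_state(), available, w)
        assert np.all(out.surface.values[:, 2:] == 0.0)
        assert np.all(out.surface.values[:, :2] > 0.0)

    def test_eligible_cell_equals_risk_reduction(self):
        g, available = self._setup()
        p = profile(g, preferred={1, 2})
        state = p.initial_state()
        w = dispersal_weight_surface(p, DispersalMode.NONE, g)
        out = species_benefit_surface(p, state, available, w)
        expected = risk_reduction(state, pixel_area_km2(g), p.z)
        assert np.all(out.surface.values == pytest.approx(expected, rel=1e-14))

    def test_zero_suitability_annihilates(self):
        g, available = self._setup()
        p = profile(g, preferred={1, 2})
        w = dispersal_weight_surface(p, DispersalMode.NONE, g)
        suit = ContinuousSurface(grid=g, values=np.zeros((4, 4)))
        out = species_benefit_surface(p, p.initial_state(), available, w, suit)
        assert np.all(out.surface.values == 0.0)

    def test_suitability_out_of_range_rejected_but_noise_clamped(self):
        g, available = self._setup()
        p = profile(g, preferred={1, 2})
        w = dispersal_weight_surface(p, DispersalMode.NONE, g)
        bad = ContinuousSurface(grid=g, values=np.full((4, 4), 1.2))
        with pytest.raises(ValueError, match="suitability"):
            species_benefit_surface(p, p.initial_state(), available, w, bad)
        noisy = ContinuousSurface(grid=g, values=np.full((4, 4), 1.0 + 5e-7))
        out = species_benefit_surface(p, p.initial_state(), available, w, noisy)
        assert np.all(out.surface.values >= 0.0)

    def test_benefit_shrinks_after_restoration(self):
        g, available = self._setup()
        p = profile(g, preferred={1, 2})
        state = p.initial_state()
        w = dispersal_weight_surface(p, DispersalMode.NONE, g)
        before = species_benefit_surface(p, state, available, w).surface.values
        state.add_restored(2.0)
        after = species_benefit_surface(p, state, available, w).surface.values
        nz = before > 0
        assert np.all(after[nz] < before[nz])

    def test_support_and_value_ordering_across_modes(self):
        g, available = self._setup()
        p = profile(g, preferred={1, 2}, dispersal=0.4, current=box(0, 0, 1000, 4000))
        state = p.initial_state()
        values = {}
        for mode in DispersalMode:
            w = dispersal_weight_surface(p, mode, g)
            values[mode] = species_benefit_surface(p, state, available, w).surface.values
        sup = {m: v > 0 for m, v in values.items()}
        assert np.array_equal(sup[DispersalMode.INTERMEDIATE], sup[DispersalMode.NONE])
        assert np.all(sup[DispersalMode.NATURAL] <= sup[DispersalMode.INTERMEDIATE])
        assert sup[DispersalMode.NATURAL].sum() < sup[DispersalMode.NONE].sum()
        assert np.all(values[DispersalMode.NATURAL] <= values[DispersalMode.INTERMEDIATE])
        assert np.all(values[DispersalMode.INTERMEDIATE] <= values[DispersalMode.NONE])


class TestAggregate:
    def _surfaces(self):
        g, available = TestSpeciesBenefit()._setup()
        p1 = profile(g, preferred={1})
        p2 = profile(g, preferred={2})
        w = dispersal_weight_surface(p1, DispersalMode.NONE, g)
        s1 = species_benefit_surface(p1, p1.initial_state(), available, w)
        s2 = species_benefit_surface(p2, p2.initial_state(), available, w)
        return s1, s2

    def test_single_species_identity(self):
        s1, _ = self._surfaces()
        total = aggregate_benefit([s1])
        assert np.array_equal(total.surface.values, s1.surface.values)

    def test_disjoint_support_union(self):
        s1, s2 = self._surfaces()
        total = aggregate_benefit([s1, s2]).surface.values
        assert np.array_equal(total > 0, (s1.surface.values > 0) | (s2.surface.values > 0))

    def test_weighted_sum_arithmetic(self):
        s1, s2 = self._surfaces()
        # force known contributions at one cell
        s1.surface.values[:] = 0.0
        s2.surface.values[:] = 0.0
        s1.surface.values[0, 0] = 0.001
        s2.surface.values[0, 0] = 0.001
        s3 = type(s2)(species="third", surface=ContinuousSurface(
            grid=s2.surface.grid, values=np.zeros((4, 4))))
        s3.surface.values[0, 0] = 0.001
        total = aggregate_benefit([s1, s2, s3], {"sp": 1.0, "third": 2.0})
        assert total.surface.values[0, 0] == pytest.approx(0.004, rel=1e-12)

    def test_order_invariance(self):
        s1, s2 = self._surfaces()
        a = aggregate_benefit([s1, s2]).surface.values
        b = aggregate_benefit([s2, s1]).surface.values
        assert np.array_equal(a, b)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_benefit([])
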