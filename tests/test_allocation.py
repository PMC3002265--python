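import numpy as np
import pytest

import landcast as lc
from landcast.allocation import (allocate_expansion, allocate_contraction,
                                 dominant_natural_class, T_URBAN_NEW,
                                 T_CROP_NEW, T_CROP_ABANDONED,
                                 T_CROP_RETAINED, AllocationInfeasibleError)
from landcast.suitability import SuitabilityMap
from landcast.world import (URBAN, CROPLAND, GRASSLAND, FOREST_BROADLEAF,
                            SHRUBLAND)
from conftest import greedy_frontier_oracle


class TestArealTargets:
    @pytest.mark.parametrize("C,g,arable,expected", [
        (100, 1.1, 200, 110),   # growth below the arable cap
        (150, 2.0, 200, 200),   # clamped to arable area
        (100, 0.9, 200, 90),    # contraction
    ])
    def test_cropland_target(self, C, g, arable, expected):
        assert lc.cropland_target(C, g, arable) == pytest.approx(expected)

    @pytest.mark.parametrize("C,Cp,CU,expected", [
        (100, 110, 10, (20, 90, 0)),   # expansion
        (100, 80, 5, (0, 80, 15)),     # contraction: abandonment
        (100, 95, 5, (0, 95, 0)),      # boundary: survivors exactly fit
    ])
    def test_decompose_cropland(self, C, Cp, CU, expected):
        assert lc.decompose_cropland(C, Cp, CU) == pytest.approx(expected)

    def test_decompose_rejects_negative(self):
        with pytest.raises(ValueError):
            lc.decompose_cropland(-1, 5, 0)
        with pytest.raises(ValueError):
            lc.decompose_cropland(10, 5, 20)  # CU > C


def _suit(score, eligible):
    return SuitabilityMap(score=score.astype(float), eligible=eligible,
                          landuse="urban", unit="country")


class TestExpansion:
    def test_zero_target_converts_nothing(self):
        lulc = np.full((4, 4), GRASSLAND)
        lulc[0, 0] = URBAN
        suit = _suit(np.arange(16).reshape(4, 4), lulc != URBAN)
        out = allocate_expansion(lulc, suit, np.ones((4, 4)), 0.0, URBAN,
                                 years=5, seed=0)
        assert not out.any()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("shape,n", [((4, 4), 3), ((6, 6), 8),
                                          ((5, 6), 12)])
    def test_matches_exhaustive_greedy_oracle(self, shape, n, seed):
        """Frontier allocation equals the single-cell greedy oracle on
        small grids with distinct suitability scores."""
        rng = np.random.default_rng(seed)
        lulc = np.full(shape, GRASSLAND)
        seed_cell = (rng.integers(shape[0]), rng.integers(shape[1]))
        lulc[seed_cell] = URBAN
        score = rng.permutation(np.arange(lulc.size, dtype=float)
                                ).reshape(shape)
        eligible = lulc != URBAN
        out = allocate_expansion(lulc, _suit(score, eligible),
                                 np.ones(shape), float(n), URBAN,
                                 years=1, seed=seed)
        oracle = greedy_frontier_oracle(score, eligible, lulc == URBAN, n)
        assert {tuple(p) for p in np.argwhere(out)} == oracle

    def test_protected_top_scorer_never_converted(self):
        lulc = np.full((4, 4), GRASSLAND)
        lulc[0, 0] = URBAN
        score = np.arange(16, dtype=float).reshape(4, 4)
        eligible = lulc != URBAN
        eligible[3, 3] = False   # the best-scoring cell is off limits
        out = allocate_expansion(lulc, _suit(score, eligible),
                                 np.ones((4, 4)), 5.0, URBAN, 1, seed=0)
        assert not out[3, 3]

    def test_infeasible_target_raises(self):
        lulc = np.full((3, 3), GRASSLAND)
        lulc[0, 0] = URBAN
        eligible = np.zeros((3, 3), bool)
        eligible[2, 2] = True
        with pytest.raises(AllocationInfeasibleError):
            allocate_expansion(lulc, _suit(np.ones((3, 3)), eligible),
                               np.ones((3, 3)), 5.0, URBAN, 1, seed=0)

    def test_no_seed_extent_waives_adjacency(self):
        lulc = np.full((4, 4), GRASSLAND)
        score = np.arange(16, dtype=float).reshape(4, 4)
        out = allocate_expansion(lulc, _suit(score, np.ones((4, 4), bool)),
                                 np.ones((4, 4)), 2.0, URBAN, 1, seed=0)
        # picks the two best cells anywhere
        assert out[3, 3] and out[3, 2]


class TestContraction:
    def test_zero_loss(self):
        lulc = np.full((3, 3), CROPLAND)
        out = allocate_contraction(lulc, np.ones((3, 3)), np.ones((3, 3)),
                                   0.0, seed=0)
        assert not out.any()

    def test_lowest_score_removed_first(self):
        lulc = np.full((1, 3), CROPLAND)
        score = np.array([[30.0, 10.0, 20.0]])
        out = allocate_contraction(lulc, score, np.ones((1, 3)), 1.0, seed=0)
        assert out[0, 1] and out.sum() == 1

    def test_abandoned_cell_takes_ecoregion_forest_class(self, fixture_small):
        world, table, crops = fixture_small
        eco = dominant_natural_class(world.lulc2000, world.ecoregion_id)
        # ecoregion 1 is forest-dominated in the fixture
        assert eco[1] == FOREST_BROADLEAF
        assert eco[2] == GRASSLAND


class TestRunAllocation:
    def test_same_seed_reproduces_transitions(self, fixture_small):
        world, table, crops = fixture_small
        cfg = lc.ScenarioConfig(scenario_name="d", seed=9)
        a1 = lc.run_allocation(world, table, cfg)
        a2 = lc.run_allocation(world, table, cfg)
        np.testing.assert_array_equal(a1.transition, a2.transition)
        np.testing.assert_array_equal(a1.lulc2015, a2.lulc2015)

    def test_urban_realized_within_one_cell_of_target(self, small_run):
        world, table = small_run.world, small_run.table
        for c in world.countries:
            realized = float(world.cell_area[small_run.allocation.urban_new
                                             & (world.country_id == c)].sum())
            target = float(small_run.table.delta_urban[c])
            assert abs(realized - target) <= world.cell_area.max()

    def test_cropland_realized_within_one_cell_of_target(self, small_run):
        tg = small_run.allocation.targets
        assert (abs(tg["realized_crop_new"] - tg["C_new"])
                <= small_run.world.cell_area.max()).all()

    def test_urban_and_cropland_mutually_exclusive(self, small_run):
        tr = small_run.allocation.transition
        assert not ((tr == T_URBAN_NEW) & (tr == T_CROP_NEW)).any()
        assert (small_run.allocation.lulc2015[tr == T_URBAN_NEW] == URBAN).all()
        assert (small_run.allocation.lulc2015[tr == T_CROP_NEW] == CROPLAND).all()

    def test_protected_cells_inviolable(self, small_run):
        prot = small_run.world.protected
        tr = small_run.allocation.transition
        assert (tr[prot] == 0).all()

    def test_urban_pattern_identical_across_scenarios(self, fixture_small):
        world, table, crops = fixture_small
        a_c = lc.run_allocation(world, table, lc.ScenarioConfig(
            scenario_name="c", allocation_unit="country", seed=5))
        a_r = lc.run_allocation(world, table, lc.ScenarioConfig(
            scenario_name="r", allocation_unit="regional", seed=5))
        np.testing.assert_array_equal(a_c.urban_new, a_r.urban_new)

    def test_new_cropland_lands_on_forest_belt(self, small_run):
        """The fixture's highest-suitability expansion frontier is the
        arable forest row, so expansion clears forest."""
        world = small_run.world
        new = small_run.allocation.transition == T_CROP_NEW
        assert new.sum() == 5
        assert (world.lulc2000[new] == FOREST_BROADLEAF).all()

    def test_abandonment_count_and_relabel(self, small_run):
        world = small_run.world
        ab = small_run.allocation.transition == T_CROP_ABANDONED
        assert ab.sum() == 4     # country 2: (20 − CU)·0.8 ⇒ 4 cells out
        assert (small_run.allocation.lulc2015[ab] == GRASSLAND).all()

    def test_converted_quality_dominates_leftover(self, small_run):
        """On the fixture (adjacency never binding) expansion takes
        higher-scoring cells than it leaves, and contraction drops
        lower-scoring cells than it keeps."""
        world = small_run.world
        suit = small_run.allocation.crop_suitability
        tr = small_run.allocation.transition
        new = tr == T_CROP_NEW
        left = suit.eligible & ~new
        assert np.nanmean(suit.score[new]) >= np.nanmean(suit.score[left])
        c2 = world.country_id == 2
        ab, kept = (tr == T_CROP_ABANDONED) & c2, (tr == T_CROP_RETAINED) & c2
        assert np.nanmean(suit.score[ab]) <= np.nanmean(suit.score[kept])
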