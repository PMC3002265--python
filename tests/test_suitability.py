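import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import landcast as lc
from landcast.suitability import yield_score, _rescale
from landcast.world import URBAN, WATER


class TestSlopeScore:
    @pytest.mark.parametrize("slope,score", [
        (0, 5), (10, 5), (11.9, 5),        # gentle terrain scores best
        (12, 4), (17.9, 4),
        (18, 3), (29.9, 3),                # lower bin edges inclusive
        (30, 2), (49.9, 2),
        (50, 1), (60, 1), (90, 1),
    ])
    def test_bins(self, slope, score):
        assert lc.slope_score(slope) == score

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            lc.slope_score(-1.0)


class TestPopDensityScore:
    @pytest.mark.parametrize("density,score", [
        (0, 1),            # uninhabited cells score the floor
        (10, 2), (25, 2),  # bins are right-closed: (0,25] → 2
        (26, 3), (50, 3),
        (60, 4), (75, 4),
        (76, 5), (100, 5),
    ])
    def test_equal_interval_bins(self, density, score):
        assert lc.popdensity_score(density, unit_max=100.0) == score

    def test_all_zero_unit_scores_one(self):
        out = lc.popdensity_score(np.zeros(5))
        np.testing.assert_array_equal(out, np.ones(5))

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            lc.popdensity_score(-5.0)


class TestYieldScore:
    def test_constant_unit_scores_midpoint(self):
        np.testing.assert_array_equal(yield_score(np.full(4, 2.5)),
                                      np.full(4, 3.0))

    def test_extremes(self):
        assert yield_score(10.0, unit_min=0.0, unit_max=10.0) == 5
        assert yield_score(0.0, unit_min=0.0, unit_max=10.0) == 1


class TestUrbanSuitability:
    def test_rescale_examples(self):
        # (avg − 1)/4 × 100 maps the 1–5 average onto 0–100
        assert _rescale(np.array(5.0)) == 100.0
        assert _rescale(np.array(1.0)) == 0.0
        assert _rescale(np.array(3.5)) == 62.5

    @given(st.lists(st.floats(1, 5), min_size=2, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_rescale_is_order_preserving(self, avgs):
        a = np.array(avgs)
        assert (np.argsort(_rescale(a), kind="stable")
                == np.argsort(a, kind="stable")).all()

    def test_protected_and_water_ineligible(self, fixture_small):
        world, _, _ = fixture_small
        smap = lc.urban_suitability(world)
        assert not smap.eligible[world.protected].any()
        assert not smap.eligible[world.lulc2000 == WATER].any()
        assert not smap.eligible[world.lulc2000 == URBAN].any()
        assert np.isnan(smap.masked_score()[world.protected]).all()

    def test_flat_dense_cell_scores_100(self, fixture_small):
        world, _, _ = fixture_small
        smap = lc.urban_suitability(world)
        # rows 0–2 have the unit-max density and <12% slope
        assert smap.score[2, 3] == 100.0


class TestIrrigationAssignment:
    def test_reference_cells_assigned_irrigated(self, fixture_small):
        world, _, _ = fixture_small
        a = lc.assign_irrigation(world, strictness=2.0)
        ref = world.irrig2000 >= 0.10
        assert a.assigned_irrigated[ref].all()
        np.testing.assert_array_equal(a.potential_yield[ref],
                                      world.yield_irrigated[ref])

    def test_country_without_irrigation_stays_rainfed(self, fixture_small):
        world, _, _ = fixture_small
        w2 = lc.make_fixture_small()[0]
        w2.irrig2000 = np.zeros(world.shape)
        a = lc.assign_irrigation(w2, strictness=2.0)
        assert not a.assigned_irrigated.any()
        np.testing.assert_array_equal(a.potential_yield, w2.yield_rainfed)

    @pytest.mark.parametrize("s_low,s_high", [(0.5, 1.0), (1.0, 2.0),
                                              (2.0, 5.0)])
    def test_monotone_in_strictness(self, fixture_small, s_low, s_high):
        world, _, _ = fixture_small
        lo = lc.assign_irrigation(world, strictness=s_low).assigned_irrigated
        hi = lc.assign_irrigation(world, strictness=s_high).assigned_irrigated
        assert (lo <= hi).all()   # smaller radius ⇒ subset

    def test_some_rainfed_cropland_remains(self, fixture_small):
        world, _, _ = fixture_small
        a = lc.assign_irrigation(world, strictness=2.0)
        crop = world.lulc2000 == lc.CROPLAND
        assert (crop & ~a.assigned_irrigated).any()


class TestCroplandSuitability:
    def test_protected_cells_ineligible(self, fixture_small):
        world, _, _ = fixture_small
        a = lc.assign_irrigation(world, strictness=2.0)
        smap = lc.cropland_suitability(world, a, unit="country")
        assert not smap.eligible[world.protected].any()
        assert np.isnan(smap.masked_score()[world.protected]).all()

    def test_normalization_is_within_unit(self, fixture_small):
        """Same cell values score differently when the unit range differs."""
        world, _, _ = fixture_small
        a = lc.assign_irrigation(world, strictness=2.0)
        by_country = lc.cropland_suitability(world, a, unit="country")
        by_region = lc.cropland_suitability(world, a, unit="region")
        # both countries share one region, so pooling the yield range
        # must change at least some scores
        both = np.isfinite(by_country.score) & np.isfinite(by_region.score)
        assert not np.array_equal(by_country.score[both],
                                  by_region.score[both])

    def test_top_yield_flat_cell_scores_100(self, fixture_small):
        world, _, _ = fixture_small
        a = lc.assign_irrigation(world, strictness=2.0)
        smap = lc.cropland_suitability(world, a, unit="country")
        best = np.nanmax(smap.score[world.country_id == 1])
        assert best == 100.0
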