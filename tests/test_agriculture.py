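import numpy as np
import pandas as pd
import pytest

import landcast as lc
from landcast.agriculture import (multicrop_weight, harvested_2015,
                                  crop_group_yield, productivity_inflator,
                                  production_2015, HarvestAreas)
from landcast.allocation import T_CROP_NEW
from landcast.world import CROPLAND, ZONE_SINGLE, ZONE_DOUBLE


class TestCroppingZones:
    def test_all_single_zone(self, fixture_small):
        world, _, _ = fixture_small
        crop1 = (world.lulc2000 == CROPLAND) & (world.country_id == 1)
        f = lc.cropping_zone_fractions(world, crop1, world.country_id)
        assert f.loc[1, "sigma1"] == 1.0 and f.loc[1, "sigma2"] == 0.0

    def test_half_double_zone(self, fixture_small):
        world, _, _ = fixture_small
        crop2 = (world.lulc2000 == CROPLAND) & (world.country_id == 2)
        f = lc.cropping_zone_fractions(world, crop2, world.country_id)
        assert f.loc[2, "sigma1"] == 0.5 and f.loc[2, "sigma2"] == 0.5

    def test_new_fractions_over_new_cells_only(self, small_run):
        world = small_run.world
        new = small_run.allocation.transition == T_CROP_NEW
        f = lc.cropping_zone_fractions(world, new, world.country_id)
        assert f.loc[1, "area"] == 5.0     # the five converted forest cells
        assert f.loc[2, "area"] == 0.0


class TestHarvested2015:
    def test_identity_when_unchanged(self):
        H, Hn, Ho = harvested_2015(100.0, 50.0, 50.0, 0.0,
                                   (1, 0), (1, 0), (0, 0))
        assert (H, Hn, Ho) == (100.0, 0.0, 100.0)

    def test_proportional_growth_all_single(self):
        H, _, _ = harvested_2015(100.0, 100.0, 120.0, 20.0,
                                 (1, 0), (1, 0), (1, 0))
        assert H == pytest.approx(120.0)

    def test_multicropping_weighted_growth(self):
        # w(0.5, 0.5)=1.5 in 2000; w(0.25, 0.75)=1.75 in 2015, same C
        H, _, _ = harvested_2015(100.0, 100.0, 100.0, 0.0,
                                 (0.5, 0.5), (0.25, 0.75), (0, 0))
        assert H == pytest.approx(100 * 1.75 / 1.5)
        assert H == pytest.approx(116.67, abs=0.01)

    def test_closure_to_1e9(self, small_run):
        t = small_run.harvest.table
        np.testing.assert_allclose(t["H_new"] + t["H_old"], t["H2015"],
                                   atol=1e-9)

    def test_zero_weighted_base_with_harvest_is_error(self):
        with pytest.raises(ValueError):
            harvested_2015(10.0, 0.0, 5.0, 5.0, (1, 0), (1, 0), (1, 0))


class TestCropGroupYield:
    def test_reported_coarse_grain_aggregate(self):
        """Maize + barley pooled: (114,998 + 73,991) Mg over
        (96,000 + 124,000) ha ⇒ 0.859 Mg ha⁻¹."""
        y = crop_group_yield([96_000, 124_000], [114_998, 73_991])
        assert y == pytest.approx(0.859, abs=5e-4)

    def test_single_crop_is_identity(self):
        assert crop_group_yield([100.0], [250.0]) == 2.5

    def test_zero_area_flagged(self):
        with pytest.raises(ValueError):
            crop_group_yield([0.0], [10.0])


class TestProductivityInflator:
    def test_reported_ratio(self):
        assert productivity_inflator(55.0, 49.0) == pytest.approx(1.12,
                                                                  abs=5e-3)

    def test_identical_means_give_unity(self):
        assert productivity_inflator(42.0, 42.0) == 1.0

    def test_empty_subset_undefined(self):
        assert np.isnan(productivity_inflator(np.nan, 49.0))


def _one_group_tables(y, gamma, R, s=1.0):
    attrs = pd.DataFrame({"yield2000": [y], "tech_growth": [gamma]},
                         index=pd.MultiIndex.from_tuples(
                             [(1, "wheat")], names=["country", "group"]))
    mix = pd.DataFrame({"wheat": [s]}, index=pd.Index([1], name="country"))
    return lc.CropGroupTable(attrs=attrs,
                             calories=pd.Series({"wheat": R}),
                             mix={"y2000": mix})


class TestProduction2015:
    def test_hand_worked_single_group(self):
        """Y=2, R=3e6, γ=1.2, ρ_o=1.12, H_old=100 km²:
        2·3e6·1.2·1.12·1e4 = 8.064e10 calories."""
        crops = _one_group_tables(2.0, 1.2, 3e6)
        harvest = HarvestAreas(table=pd.DataFrame(
            {"H2000": [100.0], "H2015": [100.0], "H_new": [0.0],
             "H_old": [100.0]}, index=pd.Index([1], name="country")))
        infl = pd.DataFrame({"rho_new": [np.nan], "rho_old": [1.12]},
                            index=pd.Index([1], name="country"))
        res = production_2015(harvest, crops, infl, q="y2000")
        assert res.table.loc[(1, "wheat"), "cal2015"] == pytest.approx(
            8.064e10, rel=1e-12)

    def test_neutral_parameters_scale_with_harvested_area(self):
        """γ=1, ρ=1, δ=1, unchanged mix: production tracks harvested
        area exactly (a 10% area gain is a 10% mass gain)."""
        crops = _one_group_tables(3.0, 1.0, 2e6)
        harvest = HarvestAreas(table=pd.DataFrame(
            {"H2000": [100.0], "H2015": [110.0], "H_new": [10.0],
             "H_old": [100.0]}, index=pd.Index([1], name="country")))
        infl = pd.DataFrame({"rho_new": [1.0], "rho_old": [1.0]},
                            index=pd.Index([1], name="country"))
        res = production_2015(harvest, crops, infl, q="y2000")
        row = res.table.loc[(1, "wheat")]
        assert row["mass2015"] / row["mass2000"] == pytest.approx(1.1,
                                                                  rel=1e-12)

    def test_nonfood_group_in_mass_not_calories(self, small_run):
        t = small_run.production.table
        oil = t.xs("oil_seeds", level="group")
        assert (oil["mass2015"] > 0).any()
        assert (oil["cal2015"] == 0).all()
        assert (oil["cal2000"] == 0).all()

    def test_mass_and_calories_linear_in_caloric_density(self, small_run):
        t = small_run.production.table
        cal = small_run.crops.calories
        for (c, g), row in t.iterrows():
            R = cal.get(g, np.nan)
            if np.isfinite(R) and g not in ("oil_seeds",):
                assert row["cal2015"] == pytest.approx(row["mass2015"] * R)

    def test_missing_country_in_mix_raises(self):
        crops = _one_group_tables(2.0, 1.0, 1e6)
        harvest = HarvestAreas(table=pd.DataFrame(
            {"H2000": [1.0], "H2015": [1.0], "H_new": [0.0], "H_old": [1.0]},
            index=pd.Index([7], name="country")))
        infl = pd.DataFrame({"rho_new": [1.0], "rho_old": [1.0]},
                            index=pd.Index([7], name="country"))
        with pytest.raises(KeyError, match="7"):
            production_2015(harvest, crops, infl, q="y2000")


def test_multicrop_weight():
    assert multicrop_weight(1.0, 0.0) == 1.0
    assert multicrop_weight(0.5, 0.5) == 1.5
    assert multicrop_weight(0.25, 0.75) == 1.75
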