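"""Harvested area and crop production accounting.

Cropland *grid-cell* area becomes harvested area through the
multi-cropping weight w(σ1, σ2) = σ1 + 2·σ2, where σ1/σ2 are the
fractions of a country's cropland cell area in single/double cropping
zones: harvested area is assumed to grow at the multi-cropping-weighted
rate of cropland cell-area growth.  Production in 2015 then scales the
year-2000 per-hectare output by technology growth γ, the land-quality
inflators ρ (ratio of mean cropland suitability of new/old cropland to
the 2000 cropland mean), the infrastructure-readiness fraction δ on new
land, and the chosen crop-mix share matrix q.  Dropping the caloric
density R_i yields production in Mg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .world import (GridWorld, CropGroupTable, CROPLAND, ZONE_SINGLE,
                    ZONE_DOUBLE, NONFOOD_GROUPS)
from .allocation import (AllocationResult, T_CROP_NEW, T_CROP_RETAINED)

KM2_TO_HA = 100.0


@dataclass
class HarvestAreas:
    """Per-country harvested areas (km², multi-counted) and zone shares."""

    table: pd.DataFrame   # index country; H2000,H2015,H_new,H_old,σ columns


@dataclass
class ProductionResult:
    """Per-(country, group) mass and caloric production, 2000 vs 2015."""

    table: pd.DataFrame   # index (country, group)
    inflators: pd.DataFrame  # per country: rho_new, rho_old

    def country_totals(self) -> pd.DataFrame:
        return self.table.groupby(level="country")[
            ["mass2000", "mass2015", "cal2000", "cal2015"]].sum()

    def global_totals(self) -> pd.Series:
        return self.table[["mass2000", "mass2015", "cal2000", "cal2015"]].sum()


def multicrop_weight(sigma1, sigma2):
    """Harvests per unit cropland area implied by the zone shares."""
    return sigma1 + 2.0 * sigma2


def cropping_zone_fractions(world: GridWorld, mask: np.ndarray,
                            by: np.ndarray) -> pd.DataFrame:
    """Area-weighted single/double-zone fractions of *mask* cells per unit."""
    rows = {}
    for u in np.unique(by[by > 0]):
        sel = mask & (by == u)
        tot = float(world.cell_area[sel].sum())
        if tot <= 0:
            rows[int(u)] = {"sigma1": 0.0, "sigma2": 0.0, "area": 0.0}
            continue
        s1 = float(world.cell_area[sel & (world.cropzone == ZONE_SINGLE)].sum())
        s2 = float(world.cell_area[sel & (world.cropzone == ZONE_DOUBLE)].sum())
        rows[int(u)] = {"sigma1": s1 / tot, "sigma2": s2 / tot, "area": tot}
    df = pd.DataFrame(rows).T
    df.index.name = "country"
    return df


def harvested_2015(H2000: float, C: float, C_prime: float, C_new: float,
                   sig: tuple, sig_p: tuple, sig_n: tuple):
    """Project 2015 harvested area and split it into new and old parts.

    ``sig``/``sig_p``/``sig_n`` are (σ1, σ2) for 2000 cropland, all 2015
    cropland, and new 2015 cropland.  Harvested area grows at the
    multi-cropping-weighted rate of cropland cell-area growth; the old
    part closes the identity H_old = H2015 − H_new.
    """
    w0 = multicrop_weight(*sig) * C
    if w0 <= 0:
        if H2000 > 0:
            raise ValueError("positive 2000 harvested area with zero "
                             "multi-cropping-weighted cropland area")
        return 0.0, 0.0, 0.0
    H2015 = H2000 * multicrop_weight(*sig_p) * C_prime / w0
    H_new = H2000 * multicrop_weight(*sig_n) * C_new / w0
    return H2015, H_new, H2015 - H_new


def harvest_areas(world: GridWorld, alloc: AllocationResult,
                  countries: pd.DataFrame) -> HarvestAreas:
    """Per-country 2015 harvested areas from the allocation outcome.

    Under the *regional* scenario the areal targets were set per region,
    but harvested-area accounting always runs per country on the
    realized maps (regional C′/C_new decompose into country values on
    the grid).
    """
    cid = world.country_id
    crop2000 = world.lulc2000 == CROPLAND
    crop2015 = alloc.lulc2015 == CROPLAND
    new = alloc.transition == T_CROP_NEW
    old = alloc.transition == T_CROP_RETAINED
    f2000 = cropping_zone_fractions(world, crop2000, cid)
    f2015 = cropping_zone_fractions(world, crop2015, cid)
    fnew = cropping_zone_fractions(world, new, cid)
    fold = cropping_zone_fractions(world, old, cid)
    rows = []
    for c in world.countries:
        H0 = float(countries["harvested2000"].get(c, 0.0))
        sig = (f2000.loc[c, "sigma1"], f2000.loc[c, "sigma2"])
        sig_p = (f2015.loc[c, "sigma1"], f2015.loc[c, "sigma2"])
        sig_n = (fnew.loc[c, "sigma1"], fnew.loc[c, "sigma2"])
        C = f2000.loc[c, "area"]
        Cp = f2015.loc[c, "area"]
        Cn = fnew.loc[c, "area"]
        if C > 0:
            H2015, H_new, H_old = harvested_2015(H0, C, Cp, Cn, sig, sig_p, sig_n)
        else:
            H2015 = H_new = H_old = 0.0
        rows.append({"country": c, "H2000": H0, "H2015": H2015,
                     "H_new": H_new, "H_old": H_old,
                     "sigma1": sig[0], "sigma2": sig[1],
                     "sigma1_2015": sig_p[0], "sigma2_2015": sig_p[1],
                     "nsigma1": sig_n[0], "nsigma2": sig_n[1],
                     "osigma1": fold.loc[c, "sigma1"],
                     "osigma2": fold.loc[c, "sigma2"]})
    return HarvestAreas(table=pd.DataFrame(rows).set_index("country"))


def crop_group_yield(areas_ha, production_mg) -> float:
    """Aggregate yield of a crop group: total mass over total area."""
    areas = np.asarray(areas_ha, dtype=float)
    prod = np.asarray(production_mg, dtype=float)
    total_area = areas.sum()
    if total_area <= 0:
        raise ValueError("crop group has zero harvested area; yield undefined")
    return float(prod.sum() / total_area)


def productivity_inflator(mean_suit_subset: float,
                          mean_suit_2000: float) -> float:
    """Land-quality inflator ρ: subset mean suitability over the 2000 mean."""
    if not np.isfinite(mean_suit_subset) or not np.isfinite(mean_suit_2000) \
            or mean_suit_2000 <= 0:
        return np.nan
    return float(mean_suit_subset / mean_suit_2000)


def suitability_inflators(world: GridWorld, alloc: AllocationResult) -> pd.DataFrame:
    """ρ_new and ρ_old per country from the cropland suitability map.

    A country with no new (or no retained) cropland gets NaN for that
    inflator; the matching production term is zero anyway.
    """
    score = alloc.crop_suitability.score
    cid = world.country_id
    crop2000 = world.lulc2000 == CROPLAND
    rows = {}
    for c in world.countries:
        in_c = cid == c
        base = score[in_c & crop2000]
        m0 = np.nanmean(base) if base.size else np.nan
        newm = score[in_c & (alloc.transition == T_CROP_NEW)]
        oldm = score[in_c & (alloc.transition == T_CROP_RETAINED)]
        rows[c] = {
            "rho_new": productivity_inflator(
                np.nanmean(newm) if newm.size else np.nan, m0),
            "rho_old": productivity_inflator(
                np.nanmean(oldm) if oldm.size else np.nan, m0),
        }
    df = pd.DataFrame(rows).T
    df.index.name = "country"
    return df


def production_2015(harvest: HarvestAreas, crops: CropGroupTable,
                    inflators: pd.DataFrame, q: str,
                    delta: float = 1.0, f=lambda rho: rho) -> ProductionResult:
    """Mass and caloric production per country and crop group.

    2015 caloric output of group i in country j is
    ``Y·R·γ·[f(ρ_n)·δ·s_n·H_new + f(ρ_o)·s_o·H_old]`` with harvested
    areas converted km² → ha; the 2000 baseline is ``Y·R·s·H2000``
    under the year-2000 mix.  Mass drops R.  Non-food groups are
    excluded from calorie totals (their R is NaN → treated as 0 cal).
    """
    s_old = crops.shares(q, new_land=False)
    s_new = crops.shares(q, new_land=True)
    s_base = crops.shares("y2000")
    rows = []
    for c in harvest.table.index:
        if c not in s_old.index:
            raise KeyError(f"crop-mix matrix {q!r} missing country {c}")
        H0 = harvest.table.loc[c, "H2000"] * KM2_TO_HA
        Hn = harvest.table.loc[c, "H_new"] * KM2_TO_HA
        Ho = harvest.table.loc[c, "H_old"] * KM2_TO_HA
        rho_n = inflators.loc[c, "rho_new"] if c in inflators.index else np.nan
        rho_o = inflators.loc[c, "rho_old"] if c in inflators.index else np.nan
        fn = f(rho_n) if np.isfinite(rho_n) else 0.0
        fo = f(rho_o) if np.isfinite(rho_o) else 0.0
        for i in s_old.columns:
            Y = crops.attrs.loc[(c, i), "yield2000"]
            gamma = crops.attrs.loc[(c, i), "tech_growth"]
            R = crops.calories.get(i, np.nan)
            food = i not in NONFOOD_GROUPS and np.isfinite(R)
            area_term = (fn * delta * s_new.loc[c, i] * Hn
                         + fo * s_old.loc[c, i] * Ho)
            mass2015 = Y * gamma * area_term
            mass2000 = Y * s_base.loc[c, i] * H0
            rows.append({
                "country": c, "group": i,
                "mass2000": mass2000, "mass2015": mass2015,
                "cal2000": mass2000 * R if food else 0.0,
                "cal2015": mass2015 * R if food else 0.0,
            })
    table = pd.DataFrame(rows).set_index(["country", "group"])
    return ProductionResult(table=table, inflators=inflators)
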