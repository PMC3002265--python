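"""Synthetic gridded worlds with internally consistent country tables.

Real scenario inputs are a stack of global rasters plus country-level
statistics.  This module emulates that stack's statistical structure at
desk scale: a few countries grouped into regions, spatially
autocorrelated slope / yield / climate surfaces (Gaussian-smoothed
noise), one contiguous urban seed cluster and a cropland belt per
country, protected patches covering 5–15% of land, and country tables
(urbanization targets, cropland growth rates, harvested area, carbon
means, HDI, deforestation baselines) that are mutually consistent with
the rasters.  :func:`make_fixture_small` builds a 12×12 two-country
world whose every downstream quantity is hand-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .world import (GridWorld, CountryTable, CropGroupTable, CROP_GROUPS,
                    WATER, URBAN, CROPLAND, FOREST_BROADLEAF, FOREST_CONIFER,
                    GRASSLAND, SHRUBLAND, WETLAND, BARREN, FOREST_CLASSES,
                    ZONE_NONE, ZONE_SINGLE, ZONE_DOUBLE, DEFAULT_KCOEF,
                    validate_world, country_tables_from_world)

#: caloric densities (cal Mg⁻¹); oil seeds are a non-food group (NaN)
DEFAULT_CALORIES = pd.Series({
    "rice": 3.6e6, "wheat": 3.3e6, "coarse_grains": 3.5e6,
    "oil_seeds": np.nan, "roots_tubers": 0.8e6, "other": 2.0e6,
})

#: base biomass carbon storage by class, Mg C ha⁻¹
CARBON_BASE = {
    WATER: 0.0, URBAN: 2.0, CROPLAND: 5.0, FOREST_BROADLEAF: 120.0,
    FOREST_CONIFER: 90.0, GRASSLAND: 30.0, SHRUBLAND: 15.0,
    WETLAND: 60.0, BARREN: 1.0,
}


@dataclass
class WorldParams:
    """Generator knobs with field-realistic defaults.

    Urban growth factors span the projected 2000–2015 urbanization range
    (global mean ≈ +24%); cropland growth rates straddle 1 so both
    expansion and contraction occur; protected patches target ~10% of
    land; the late precipitation epoch is the early one times a smooth
    field in [0.7, 1.3] so water-yield change takes both signs.
    """

    shape: tuple = (100, 100)
    n_countries: int = 4
    n_regions: int = 2
    n_ecoregions: int = 6
    n_basins: int = 3
    cell_area_km2: float = 1.0
    urban_growth: tuple = (1.15, 1.35)
    crop_rate_range: tuple = (0.85, 1.30)
    region_rate_range: tuple = (0.90, 1.25)
    protected_fraction: float = 0.10
    smooth_sigma: float = 4.0
    n_unclassified_hdi: int = 0


class GenerationError(RuntimeError):
    """Could not generate a feasible world within the retry budget."""


def _smooth(rng, shape, sigma):
    """Standardized Gaussian-smoothed white noise."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return (f - f.mean()) / (f.std() + 1e-12)


def _unit(f):
    """Squash a standardized field into (0, 1)."""
    return 1.0 / (1.0 + np.exp(-f))


def _voronoi(rng, shape, n):
    """Nearest-seed label map, labels 1..n."""
    ny, nx = shape
    pts = np.column_stack([rng.uniform(0, ny, n), rng.uniform(0, nx, n)])
    yy, xx = np.mgrid[0:ny, 0:nx]
    d = (yy[..., None] - pts[:, 0]) ** 2 + (xx[..., None] - pts[:, 1]) ** 2
    return np.argmin(d, axis=-1).astype(np.int32) + 1


def generate_world(params: WorldParams | None = None, seed: int = 0,
                   max_retries: int = 5):
    """Generate a (GridWorld, CountryTable, CropGroupTable) triple.

    Deterministic in ``seed``.  If a country's drawn urbanization target
    exceeds its eligible area the targets are shrunk and generation
    retried, up to ``max_retries`` times.
    """
    params = params or WorldParams()
    ny, nx = params.shape
    if ny < 20 or nx < 20:
        raise ValueError("grid must be at least 20×20")
    if params.n_countries < 2 or params.n_ecoregions < 2:
        raise ValueError("need at least 2 countries and 2 ecoregions")

    shrink = 1.0
    for _ in range(max_retries):
        try:
            return _generate(params, seed, shrink)
        except GenerationError:
            shrink *= 0.5
    raise GenerationError("could not satisfy urbanization targets after "
                          f"{max_retries} retries")


def _generate(params: WorldParams, seed: int, shrink: float):
    rng = np.random.default_rng(seed)
    shape = params.shape
    sig = params.smooth_sigma

    country_id = _voronoi(rng, shape, params.n_countries)
    region_of = {c: (c - 1) % params.n_regions + 1
                 for c in range(1, params.n_countries + 1)}
    region_id = np.vectorize(region_of.get)(country_id).astype(np.int32)
    ecoregion_id = _voronoi(rng, shape, params.n_ecoregions)
    basin_id = _voronoi(rng, shape, params.n_basins)

    slope = np.clip(45.0 * np.abs(_smooth(rng, shape, sig)), 0.0, 90.0)
    yr_field = _unit(_smooth(rng, shape, sig))
    yield_rainfed = 1.0 + 8.0 * yr_field
    yield_irrigated = yield_rainfed * (1.1 + 0.4 * _unit(_smooth(rng, shape, sig)))
    precip_e1 = 400.0 + 1100.0 * _unit(_smooth(rng, shape, sig))
    precip_e2 = precip_e1 * (0.7 + 0.6 * _unit(_smooth(rng, shape, sig)))
    eto = 700.0 + 700.0 * _unit(_smooth(rng, shape, sig))
    awc = 40.0 + 160.0 * _unit(_smooth(rng, shape, sig))

    # natural land cover from a vegetation field + moisture
    veg = _smooth(rng, shape, sig)
    lulc = np.full(shape, GRASSLAND, dtype=np.int32)
    lulc[veg > 0.6] = FOREST_BROADLEAF
    lulc[(veg > 0.2) & (veg <= 0.6) & (precip_e1 < 800)] = FOREST_CONIFER
    lulc[(veg > 0.2) & (veg <= 0.6) & (precip_e1 >= 800)] = FOREST_BROADLEAF
    lulc[veg < -1.0] = SHRUBLAND
    lulc[veg < -1.8] = BARREN
    wet = _smooth(rng, shape, sig / 2)
    lulc[(wet > 1.6) & (precip_e1 > 900)] = WETLAND
    lulc[wet < -2.2] = WATER

    # urban seed cluster per country at its population centre
    popdens = np.zeros(shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for c in range(1, params.n_countries + 1):
        in_c = country_id == c
        interior = ndimage.binary_erosion(in_c, iterations=2)
        cand = interior & (lulc != WATER)
        if not cand.any():
            cand = in_c & (lulc != WATER)
        idx = rng.choice(np.flatnonzero(cand))
        r0, c0 = np.unravel_index(idx, shape)
        rad = max(1, min(shape) // 40)
        block = (np.abs(yy - r0) <= rad) & (np.abs(xx - c0) <= rad) & in_c
        lulc[block] = URBAN
        d2 = (yy - r0) ** 2 + (xx - c0) ** 2
        popdens += in_c * 400.0 * np.exp(-d2 / (2 * (max(shape) / 6) ** 2))
    popdens *= np.clip(1.0 + 0.5 * _smooth(rng, shape, sig / 2), 0.0, None)
    popdens[lulc == WATER] = 0.0

    # cropland belt per country: a latitudinal band around the urban seed
    for c in range(1, params.n_countries + 1):
        in_c = (country_id == c) & (lulc != WATER) & (lulc != URBAN)
        rows = np.nonzero(in_c.any(axis=1))[0]
        if rows.size == 0:
            continue
        mid = int(np.median(rows))
        half = max(2, (rows[-1] - rows[0]) // 6)
        band = in_c & (np.abs(yy - mid) <= half) & (slope < 30)
        lulc[band] = CROPLAND

    arable = ((lulc == CROPLAND)
              | ((slope < 30) & (lulc != WATER) & (lulc != URBAN)
                 & (yield_rainfed > np.quantile(yield_rainfed, 0.25))))

    # protected patches (never on cropland or urban)
    protected = np.zeros(shape, dtype=bool)
    land = lulc != WATER
    target = params.protected_fraction * land.sum()
    tries = 0
    while protected.sum() < target and tries < 200:
        idx = rng.choice(np.flatnonzero(land & (lulc != URBAN)
                                        & (lulc != CROPLAND)))
        r0, c0 = np.unravel_index(idx, shape)
        rad = rng.integers(2, max(3, min(shape) // 12))
        patch = ((yy - r0) ** 2 + (xx - c0) ** 2 <= rad ** 2) \
            & (lulc != URBAN) & (lulc != CROPLAND)
        protected |= patch
        tries += 1

    irrig = np.clip(_smooth(rng, shape, sig / 2) * 0.25 + 0.1, 0.0, 1.0)
    irrig[lulc != CROPLAND] *= 0.2
    irrig[lulc == WATER] = 0.0

    cropzone = np.where(lulc == WATER, ZONE_NONE,
                        np.where(precip_e1 > 1000, ZONE_DOUBLE, ZONE_SINGLE)
                        ).astype(np.int32)

    carbon = np.zeros(shape)
    for cls, base in CARBON_BASE.items():
        sel = lulc == cls
        carbon[sel] = base
    carbon *= np.clip(1.0 + 0.2 * _smooth(rng, shape, sig), 0.5, 1.5)

    cell_area = np.full(shape, params.cell_area_km2)
    zconst = {int(b): float(rng.uniform(1.0, 10.0))
              for b in np.unique(basin_id)}

    world = GridWorld(
        lulc2000=lulc, slope=slope, popdens2015=popdens,
        yield_rainfed=yield_rainfed, yield_irrigated=yield_irrigated,
        irrig2000=irrig, precip_e1=precip_e1, precip_e2=precip_e2,
        eto=eto, awc=awc, carbon2000=carbon, protected=protected,
        arable=arable, country_id=country_id, region_id=region_id,
        ecoregion_id=ecoregion_id, basin_id=basin_id, cropzone=cropzone,
        cell_area=cell_area, kcoef=dict(DEFAULT_KCOEF), zconst=zconst,
    )

    table = _country_table(world, params, rng, region_of, shrink)
    crops = _crop_table(world, table, rng)
    validate_world(world, table, crops)
    return world, table, crops


def _country_table(world, params, rng, region_of, shrink):
    rows = {}
    ca = world.cell_area
    for c in world.countries:
        in_c = world.country_id == c
        urban = float(ca[in_c & (world.lulc2000 == URBAN)].sum())
        growth = rng.uniform(*params.urban_growth)
        dU = urban * (growth - 1.0) * shrink
        eligible = in_c & ~world.protected & (world.lulc2000 != WATER) \
            & (world.lulc2000 != URBAN)
        if dU > float(ca[eligible].sum()):
            raise GenerationError(f"urban target infeasible in country {c}")
        crop = world.lulc2000 == CROPLAND
        zone_w = np.where(world.cropzone == ZONE_DOUBLE, 2.0,
                          np.where(world.cropzone == ZONE_SINGLE, 1.0, 0.0))
        weighted = float((ca * zone_w)[in_c & crop].sum())
        rows[c] = {
            "region_id": region_of[c],
            "hdi": float(rng.uniform(0.30, 0.95)),
            "urban2000_area": urban,
            "urban2015_target": urban + dU,
            "crop_rate": float(rng.uniform(*params.crop_rate_range)),
            "harvested2000": weighted * float(rng.uniform(0.5, 0.9)),
            "forest2000": float(ca[in_c & np.isin(world.lulc2000,
                                                  FOREST_CLASSES)].sum()),
            "baseline_defor": float(rng.uniform(0.0, 0.01)),
            "ag_npv": float(rng.uniform(500.0, 20000.0)),
        }
    df = pd.DataFrame(rows).T
    df.index.name = "country"
    df["region_id"] = df["region_id"].astype(int)
    for i, c in enumerate(sorted(df.index, reverse=True)):
        if i < params.n_unclassified_hdi:
            df.loc[c, "hdi"] = np.nan
    df = df.join(country_tables_from_world(world))
    regions = pd.DataFrame({
        "crop_rate": {r: float(rng.uniform(*params.region_rate_range))
                      for r in world.regions}})
    regions.index.name = "region"
    eco = pd.DataFrame({
        "endangered_fraction": {int(e): float(rng.uniform(0.0, 0.5))
                                for e in np.unique(
                                    world.ecoregion_id[world.ecoregion_id > 0])}})
    eco.index.name = "ecoregion"
    return CountryTable(countries=df, regions=regions, ecoregions=eco)


def _crop_table(world, table, rng):
    base_yield = {"rice": 3.0, "wheat": 2.5, "coarse_grains": 2.0,
                  "oil_seeds": 1.5, "roots_tubers": 10.0, "other": 4.0}
    recs = []
    for c in world.countries:
        hdi = table.countries.loc[c, "hdi"]
        lvl = 0.6 if not np.isfinite(hdi) else 0.4 + hdi
        for g in CROP_GROUPS:
            recs.append({"country": c, "group": g,
                         "yield2000": base_yield[g] * lvl
                         * float(rng.uniform(0.8, 1.2)),
                         "tech_growth": float(rng.uniform(1.0, 1.5))})
    attrs = pd.DataFrame(recs).set_index(["country", "group"])
    mix_base = {}
    for c in world.countries:
        shares = rng.dirichlet(np.ones(len(CROP_GROUPS)) * 2.0)
        mix_base[c] = dict(zip(CROP_GROUPS, shares))
    base = pd.DataFrame(mix_base).T
    base.index.name = "country"
    return CropGroupTable(attrs=attrs, calories=DEFAULT_CALORIES.copy(),
                          mix=derive_mix_variants(base))


def derive_mix_variants(base: pd.DataFrame) -> dict:
    """The five crop-mix matrices from a year-2000 base matrix.

    ``low``/``mean`` shrink the non-staple shares steeply/moderately,
    ``near2000`` barely perturbs them, ``projected2015`` shrinks them an
    intermediate amount; the freed share is redistributed over the
    staple groups (rice, wheat, coarse grains, oil seeds) in proportion
    to their base shares.  Every row keeps summing to 1.
    """
    staples = ["rice", "wheat", "coarse_grains", "oil_seeds"]
    others = [g for g in base.columns if g not in staples]
    out = {"y2000": base.copy()}
    for name, keep in (("low", 0.3), ("mean", 0.6), ("near2000", 0.95),
                       ("projected2015", 0.7)):
        m = base.copy()
        freed = m[others].sum(axis=1) * (1.0 - keep)
        m[others] = m[others] * keep
        w = m[staples].div(m[staples].sum(axis=1), axis=0).fillna(1.0 / len(staples))
        m[staples] = m[staples] + w.mul(freed, axis=0)
        out[name] = m.div(m.sum(axis=1), axis=0)
    return out


def make_fixture_small():
    """Hand-set 12×12 two-country world for exact worked-example tests.

    Country 1 (columns 0–5, developing, HDI 0.45): 2 urban cells with a
    protected neighbour, a 20-cell cropland block (rows 6–9 × cols 0–4),
    a forest belt whose row 5 is arable — so cropland growth (g = 1.25,
    arable area 40 km² ⇒ 2015 target 25 km²) clears 5 forest cells, the
    REDD-creditable conversion.  Country 2 (columns 6–11, developed,
    HDI 0.92): g = 0.8 forces abandonment of 4 cropland cells; rows 6–7
    of its cropland are double-cropping.  Early-epoch precipitation is
    1000 mm everywhere; the late epoch is 900 mm over country 1 and
    1100 mm over country 2, so water-yield change takes both signs.
    """
    shape = (12, 12)
    yy, xx = np.mgrid[0:12, 0:12]
    c1 = xx <= 5
    country_id = np.where(c1, 1, 2).astype(np.int32)
    region_id = np.ones(shape, dtype=np.int32)

    lulc = np.full(shape, GRASSLAND, dtype=np.int32)
    # country 1
    lulc[0, 0] = lulc[0, 1] = URBAN
    lulc[1, 0] = FOREST_BROADLEAF            # protected forest by the seed
    lulc[2:6, 0:6] = FOREST_BROADLEAF        # rows 2–5
    lulc[6:10, 0:5] = CROPLAND
    lulc[10:12, 0:6] = SHRUBLAND
    # country 2
    lulc[0, 11] = URBAN
    lulc[1:5, 6:12] = FOREST_CONIFER
    lulc[6:10, 6:11] = CROPLAND
    lulc[10, 11] = lulc[11, 11] = WATER

    protected = np.zeros(shape, dtype=bool)
    protected[1, 0] = True                   # adjacent to country 1 urban seed
    protected[10, 5] = protected[11, 5] = True
    protected[5, 6] = protected[5, 7] = True

    slope = np.full(shape, 5.0)
    slope[10:12, :] = 35.0

    popdens = np.zeros(shape)
    popdens[0:3, :] = 100.0
    popdens[3:6, :] = 50.0
    popdens[6:10, :] = 10.0
    popdens[lulc == WATER] = 0.0

    yield_rainfed = np.full(shape, 4.0)
    yield_rainfed[0:6, :] = 6.0
    yield_rainfed[10:12, :] = 2.0
    yield_rainfed = yield_rainfed + 0.1 * xx   # column gradient separates
    yield_irrigated = yield_rainfed + 2.0      # irrigation look-alikes

    irrig = np.zeros(shape)
    irrig[6, 0] = irrig[6, 1] = 0.5
    irrig[6, 6] = 0.3

    precip_e1 = np.full(shape, 1000.0)
    precip_e2 = np.where(c1, 900.0, 1100.0)
    eto = np.full(shape, 1000.0)
    awc = np.full(shape, 100.0)

    arable = np.zeros(shape, dtype=bool)
    arable[5:12, 0:6] = True      # 42 cells, 2 protected ⇒ A₁ = 40 km²
    arable[5:12, 6:12] = True
    arable[lulc == WATER] = False  # drops (10,11), (11,11)

    cropzone = np.full(shape, ZONE_SINGLE, dtype=np.int32)
    cropzone[6:8, 6:11] = ZONE_DOUBLE
    cropzone[lulc == WATER] = ZONE_NONE

    carbon = np.zeros(shape)
    for cls, base in CARBON_BASE.items():
        carbon[lulc == cls] = base
    carbon[np.isin(lulc, FOREST_CLASSES)] = 100.0  # both forest types

    ecoregion_id = np.where(yy <= 5, 1, 2).astype(np.int32)
    basin_id = country_id.copy()
    cell_area = np.ones(shape)

    world = GridWorld(
        lulc2000=lulc, slope=slope, popdens2015=popdens,
        yield_rainfed=yield_rainfed, yield_irrigated=yield_irrigated,
        irrig2000=irrig, precip_e1=precip_e1, precip_e2=precip_e2,
        eto=eto, awc=awc, carbon2000=carbon, protected=protected,
        arable=arable, country_id=country_id, region_id=region_id,
        ecoregion_id=ecoregion_id, basin_id=basin_id, cropzone=cropzone,
        cell_area=cell_area, kcoef=dict(DEFAULT_KCOEF),
        zconst={1: 5.0, 2: 8.0},
    )

    countries = pd.DataFrame({
        1: {"region_id": 1, "hdi": 0.45, "urban2000_area": 2.0,
            "urban2015_target": 4.0, "crop_rate": 1.25,
            "harvested2000": 15.0, "baseline_defor": 0.005,
            "ag_npv": 5000.0},
        2: {"region_id": 1, "hdi": 0.92, "urban2000_area": 1.0,
            "urban2015_target": 3.0, "crop_rate": 0.8,
            "harvested2000": 25.0, "baseline_defor": 0.0,
            "ag_npv": 20000.0},
    }).T
    countries.index.name = "country"
    countries["region_id"] = countries["region_id"].astype(int)
    countries["forest2000"] = [
        float(world.cell_area[(world.country_id == c)
                              & np.isin(lulc, FOREST_CLASSES)].sum())
        for c in (1, 2)]
    countries = countries.join(country_tables_from_world(world))
    regions = pd.DataFrame({"crop_rate": {1: 1.1}})
    regions.index.name = "region"
    eco = pd.DataFrame({"endangered_fraction": {1: 0.4, 2: 0.1}})
    eco.index.name = "ecoregion"
    table = CountryTable(countries=countries, regions=regions, ecoregions=eco)

    yields = {"rice": 3.0, "wheat": 2.5, "coarse_grains": 2.0,
              "oil_seeds": 1.5, "roots_tubers": 10.0, "other": 4.0}
    tech = {1: 1.2, 2: 1.1}
    recs = [{"country": c, "group": g, "yield2000": y, "tech_growth": tech[c]}
            for c in (1, 2) for g, y in yields.items()]
    attrs = pd.DataFrame(recs).set_index(["country", "group"])
    base = pd.DataFrame(
        {g: {1: s, 2: s} for g, s in
         zip(CROP_GROUPS, (0.3, 0.2, 0.2, 0.1, 0.1, 0.1))})
    base.index.name = "country"
    crops = CropGroupTable(attrs=attrs, calories=DEFAULT_CALORIES.copy(),
                           mix=derive_mix_variants(base))
    validate_world(world, table, crops)
    return world, table, crops
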