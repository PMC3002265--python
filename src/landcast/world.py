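"""Core spatial containers: the gridded world and its country-level tables.

A :class:`GridWorld` is the single source of spatial truth for a scenario
run: a stack of co-registered rasters (land cover, slope, population
density, potential yields, irrigation intensity, climate surfaces, soil
water, masks and zone identifiers) plus the per-class evapotranspiration
coefficients and per-basin Budyko calibration constants.  Country-level
scalars (urbanization targets, cropland growth rates, harvested area,
deforestation baselines, carbon means, HDI, agricultural NPV) live in a
:class:`CountryTable`; per-crop-group attributes (yields, technology
growth, caloric densities, crop-mix share matrices) in a
:class:`CropGroupTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Land-use / land-cover class codes.  Two forest types so that REDD
# accounting can carry per-forest-type carbon densities.
WATER = 0
URBAN = 1
CROPLAND = 2
FOREST_BROADLEAF = 3
FOREST_CONIFER = 4
GRASSLAND = 5
SHRUBLAND = 6
WETLAND = 7
BARREN = 8

FOREST_CLASSES = (FOREST_BROADLEAF, FOREST_CONIFER)
#: "Less-intensively managed" classes: everything that is neither urban
#: nor cropland.  Used for the natural-land carbon mean and, by default,
#: as the undeveloped-land (habitat proxy) definition.
NATURAL_CLASSES = (WATER, FOREST_BROADLEAF, FOREST_CONIFER, GRASSLAND,
                   SHRUBLAND, WETLAND, BARREN)
ALL_CLASSES = (WATER, URBAN, CROPLAND) + NATURAL_CLASSES[1:]

CLASS_NAMES = {
    WATER: "water", URBAN: "urban", CROPLAND: "cropland",
    FOREST_BROADLEAF: "forest_broadleaf", FOREST_CONIFER: "forest_conifer",
    GRASSLAND: "grassland", SHRUBLAND: "shrubland", WETLAND: "wetland",
    BARREN: "barren",
}

# Cropping-zone codes (how many harvests a year the zone supports).
ZONE_NONE = 0
ZONE_SINGLE = 1
ZONE_DOUBLE = 2

#: Default crop groups.  ``oil_seeds`` is treated as a non-food group and
#: excluded from caloric totals (it still contributes to mass totals).
CROP_GROUPS = ("rice", "wheat", "coarse_grains", "oil_seeds",
               "roots_tubers", "other")
NONFOOD_GROUPS = ("oil_seeds",)

#: Default plant evapotranspiration coefficients k by LULC class.
#: Forests transpire most, barren/urban least; cropland near reference.
DEFAULT_KCOEF = {
    WATER: 1.0, URBAN: 0.3, CROPLAND: 0.65, FOREST_BROADLEAF: 1.0,
    FOREST_CONIFER: 0.95, GRASSLAND: 0.65, SHRUBLAND: 0.55,
    WETLAND: 1.1, BARREN: 0.2,
}

INT_NODATA = -1


@dataclass
class GridWorld:
    """Co-registered raster stack plus per-class and per-basin constants.

    All rasters share one shape; integer rasters use ``-1`` as nodata,
    continuous rasters use NaN.  Areas are km²; yields Mg ha⁻¹; water
    variables mm yr⁻¹; carbon Mg C ha⁻¹.
    """

    lulc2000: np.ndarray          # int class codes
    slope: np.ndarray             # percent
    popdens2015: np.ndarray       # persons km⁻²
    yield_rainfed: np.ndarray     # Mg ha⁻¹ potential cereal yield
    yield_irrigated: np.ndarray   # Mg ha⁻¹
    irrig2000: np.ndarray         # fraction of cell irrigated in 2000
    precip_e1: np.ndarray         # mm, early climate epoch (goes with 2000 LULC)
    precip_e2: np.ndarray         # mm, late epoch (goes with 2015 LULC)
    eto: np.ndarray               # mm, reference evapotranspiration
    awc: np.ndarray               # mm, plant-available water content
    carbon2000: np.ndarray        # Mg C ha⁻¹ aboveground+belowground biomass
    protected: np.ndarray         # bool, IUCN I–VI
    arable: np.ndarray            # bool
    country_id: np.ndarray        # int, 0 = no country
    region_id: np.ndarray        # int, 0 = no region
    ecoregion_id: np.ndarray      # int
    basin_id: np.ndarray          # int
    cropzone: np.ndarray          # 0 none / 1 single / 2 double
    cell_area: np.ndarray         # km² per cell
    kcoef: dict = field(default_factory=lambda: dict(DEFAULT_KCOEF))
    zconst: dict = field(default_factory=dict)   # basin_id -> Z

    @property
    def shape(self):
        return self.lulc2000.shape

    @property
    def countries(self):
        ids = np.unique(self.country_id)
        return [int(c) for c in ids if c > 0]

    @property
    def regions(self):
        ids = np.unique(self.region_id)
        return [int(r) for r in ids if r > 0]

    def kcoef_map(self, lulc: np.ndarray) -> np.ndarray:
        """Per-cell evapotranspiration coefficient for a class raster."""
        out = np.full(lulc.shape, np.nan)
        for cls, k in self.kcoef.items():
            out[lulc == cls] = k
        return out

    def zconst_map(self) -> np.ndarray:
        out = np.full(self.shape, np.nan)
        for b, z in self.zconst.items():
            out[self.basin_id == b] = z
        return out

    def class_area(self, lulc: np.ndarray, classes, mask=None) -> float:
        """Total km² of cells whose class is in *classes* (within *mask*)."""
        sel = np.isin(lulc, np.atleast_1d(classes))
        if mask is not None:
            sel &= mask
        return float(self.cell_area[sel].sum())


@dataclass
class CountryTable:
    """Country-level scalars plus regional cropland growth rates.

    ``countries`` is indexed by country id with columns: ``region_id``,
    ``hdi`` (NaN = unclassified), ``urban2000_area``, ``urban2015_target``,
    ``crop_rate`` (g_j), ``harvested2000`` (H_j, km², multi-counted),
    ``forest2000`` (km²), ``baseline_defor`` (fraction yr⁻¹), ``ag_npv``
    (currency ha⁻¹), ``carbon_urban``, ``carbon_crop``, ``carbon_natural``
    and ``carbon_forest_<k>`` (Mg C ha⁻¹).  ``regions`` is indexed by
    region id with a ``crop_rate`` (g_r) column.
    """

    countries: pd.DataFrame
    regions: pd.DataFrame
    #: optional per-ecoregion attributes (endangered_fraction column)
    ecoregions: pd.DataFrame | None = None

    @property
    def delta_urban(self) -> pd.Series:
        d = self.countries["urban2015_target"] - self.countries["urban2000_area"]
        return d.clip(lower=0.0)


@dataclass
class CropGroupTable:
    """Per-(country, crop-group) yields and growth plus crop-mix matrices.

    ``attrs``: DataFrame indexed by (country_id, group) with ``yield2000``
    (Y_ji, Mg ha⁻¹) and ``tech_growth`` (γ_ji ≥ 1).  ``calories``: Series
    of caloric densities R_i (cal Mg⁻¹), NaN for non-food groups excluded
    from calorie totals.  ``mix``: mapping q-name -> DataFrame (country ×
    group) of harvested-area shares summing to 1 per country; ``mix_new``
    optionally gives separate shares for newly established harvested area
    (defaults to ``mix`` — the old-land and new-land mixes coincide).
    """

    attrs: pd.DataFrame
    calories: pd.Series
    mix: dict
    mix_new: dict | None = None

    def shares(self, q: str, new_land: bool = False) -> pd.DataFrame:
        src = self.mix_new if (new_land and self.mix_new) else self.mix
        if q not in src:
            raise KeyError(f"unknown crop-mix id {q!r}")
        return src[q]


class WorldInvariantError(ValueError):
    """A GridWorld/table stack violates a structural invariant."""


def validate_world(world: GridWorld, table: CountryTable | None = None,
                   crops: CropGroupTable | None = None) -> None:
    """Check structural invariants; raise :class:`WorldInvariantError`.

    Checks raster co-registration, value ranges, the irrigated ≥ rainfed
    yield ordering, country→region functionality, cropping-zone coverage
    of cropland, and (when tables are given) share normalisation and
    non-negative urbanization targets.
    """
    shape = world.lulc2000.shape
    rasters = ["slope", "popdens2015", "yield_rainfed", "yield_irrigated",
               "irrig2000", "precip_e1", "precip_e2", "eto", "awc",
               "carbon2000", "protected", "arable", "country_id",
               "region_id", "ecoregion_id", "basin_id", "cropzone",
               "cell_area"]
    for name in rasters:
        arr = getattr(world, name)
        if arr.shape != shape:
            raise WorldInvariantError(
                f"raster {name!r} shape {arr.shape} != world shape {shape}")

    land = world.country_id > 0
    ir = world.irrig2000[land]
    if np.any((ir < 0) | (ir > 1)):
        raise WorldInvariantError("irrig2000 outside [0, 1]")
    both = land & np.isfinite(world.yield_rainfed) & np.isfinite(world.yield_irrigated)
    if np.any(world.yield_irrigated[both] < world.yield_rainfed[both] - 1e-12):
        raise WorldInvariantError("yield_irrigated < yield_rainfed somewhere")
    if np.any(world.slope[land] < 0):
        raise WorldInvariantError("negative slope")

    # every country maps to exactly one region
    for c in world.countries:
        regs = np.unique(world.region_id[world.country_id == c])
        if len(regs) != 1:
            raise WorldInvariantError(f"country {c} spans regions {regs}")

    crop = world.lulc2000 == CROPLAND
    if np.any(world.cropzone[crop] == ZONE_NONE):
        raise WorldInvariantError("cropland cell with cropzone 'none'")

    missing_z = set(np.unique(world.basin_id[land])) - set(world.zconst)
    if missing_z:
        raise WorldInvariantError(f"basins without Z constant: {missing_z}")

    if table is not None:
        if (table.countries["urban2015_target"]
                < table.countries["urban2000_area"] - 1e-9).any():
            raise WorldInvariantError("urban target below 2000 area (ΔU < 0)")
        if (table.countries["crop_rate"] <= 0).any():
            raise WorldInvariantError("non-positive cropland growth rate")
    if crops is not None:
        for q, df in crops.mix.items():
            if not np.allclose(df.sum(axis=1), 1.0, atol=1e-9):
                raise WorldInvariantError(f"crop-mix {q!r} rows do not sum to 1")
        bad = crops.attrs["tech_growth"] < 1 - 1e-12
        if bad.any():
            raise WorldInvariantError("technology growth factor below 1")


def country_tables_from_world(world: GridWorld, lulc=None) -> pd.DataFrame:
    """Recompute per-country, per-class area-weighted carbon means.

    Returns a DataFrame indexed by country with carbon_urban/crop/natural
    and carbon_forest_<k> columns; countries lacking a class fall back to
    the global area-weighted mean for that class.
    """
    from .carbon import mean_storage_by_class
    return mean_storage_by_class(world.carbon2000,
                                 world.lulc2000 if lulc is None else lulc,
                                 world.country_id, world.cell_area)
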