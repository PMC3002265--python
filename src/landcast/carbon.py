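"""Biomass-carbon stock change from land conversion.

The 2015 stock on converting cells is approximated by country-level
per-class mean storage (new urban and cropland attain the country's
2000 urban/cropland means; abandoned cropland attains the mean of the
less-intensively-managed classes), while the 2000 stock Z_j on those
same cells is read from the per-cell storage map.  Cells that do not
change class contribute nothing — this is a conversion-only metric, not
a full carbon budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .world import (GridWorld, URBAN, CROPLAND, FOREST_CLASSES,
                    NATURAL_CLASSES)
from .allocation import (AllocationResult, T_URBAN_NEW, T_CROP_NEW,
                         T_CROP_ABANDONED)

KM2_TO_HA = 100.0


@dataclass
class CarbonResult:
    table: pd.DataFrame        # per country: Z_j, areas, delta (Mg C)
    storage2000: np.ndarray    # Mg C ha⁻¹ per cell
    storage2015: np.ndarray    # Mg C ha⁻¹ per cell, class means on converts

    @property
    def global_delta(self) -> float:
        return float(self.table["delta"].sum())


def mean_storage_by_class(storage: np.ndarray, lulc: np.ndarray,
                          country_id: np.ndarray,
                          cell_area: np.ndarray) -> pd.DataFrame:
    """Area-weighted mean biomass carbon per country for urban, cropland,
    natural (all less-intensively managed) classes and each forest type.

    Countries lacking a class fall back to the global mean for that
    class (0 if the class is absent globally).
    """
    groups = {"carbon_urban": [URBAN], "carbon_crop": [CROPLAND],
              "carbon_natural": list(NATURAL_CLASSES)}
    for k in FOREST_CLASSES:
        groups[f"carbon_forest_{k}"] = [k]

    def wmean(sel):
        w = cell_area[sel]
        return float(np.nansum(storage[sel] * w) / w.sum()) if sel.any() else np.nan

    global_means = {name: wmean(np.isin(lulc, cls) & (country_id > 0))
                    for name, cls in groups.items()}
    rows = {}
    for c in np.unique(country_id[country_id > 0]):
        in_c = country_id == c
        row = {}
        for name, cls in groups.items():
            m = wmean(np.isin(lulc, cls) & in_c)
            if not np.isfinite(m):
                m = global_means[name]
            row[name] = m if np.isfinite(m) else 0.0
        rows[int(c)] = row
    df = pd.DataFrame(rows).T
    df.index.name = "country"
    return df


def carbon_delta(world: GridWorld, alloc: AllocationResult,
                 means: pd.DataFrame) -> CarbonResult:
    """Country-level biomass-carbon change (Mg C) due to conversion.

    delta_j = [a_urb·z̄_u + a_crop·z̄_c − Z_j] + a_aband·(z̄_l − z̄_c),
    with areas in hectares, Z_j the 2000 per-cell storage summed over the
    urban- and cropland-converting cells, and z̄ the country class means.
    """
    tr = alloc.transition
    if tr.shape != world.country_id.shape:
        raise ValueError("transition raster and country mask shapes differ")
    storage2015 = world.carbon2000.copy()
    rows = []
    for c in world.countries:
        in_c = world.country_id == c
        to_urb = in_c & (tr == T_URBAN_NEW)
        to_crop = in_c & (tr == T_CROP_NEW)
        aband = in_c & (tr == T_CROP_ABANDONED)
        a_urb = float(world.cell_area[to_urb].sum()) * KM2_TO_HA
        a_crop = float(world.cell_area[to_crop].sum()) * KM2_TO_HA
        a_aband = float(world.cell_area[aband].sum()) * KM2_TO_HA
        Z = float(np.nansum(world.carbon2000[to_urb | to_crop]
                            * world.cell_area[to_urb | to_crop])) * KM2_TO_HA
        zu = means.loc[c, "carbon_urban"]
        zc = means.loc[c, "carbon_crop"]
        zl = means.loc[c, "carbon_natural"]
        delta = (a_urb * zu + a_crop * zc - Z) + a_aband * (zl - zc)
        storage2015[to_urb] = zu
        storage2015[to_crop] = zc
        storage2015[aband] = zl
        rows.append({"country": c, "Z_j": Z, "area_to_urban_ha": a_urb,
                     "area_to_crop_ha": a_crop, "area_abandoned_ha": a_aband,
                     "delta": delta})
    table = pd.DataFrame(rows).set_index("country")
    return CarbonResult(table=table, storage2000=world.carbon2000,
                        storage2015=storage2015)
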