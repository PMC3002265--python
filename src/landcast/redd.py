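"""Avoided-deforestation (REDD) crediting with bang-bang participation.

A developing country is eligible when its scenario-projected annualized
deforestation rate exceeds its historical baseline.  Its credit cap is
the above-baseline share of the CO2e embodied in forest projected to be
cleared for cropland (urban-driven clearing is never creditable: urban
land value is assumed to dominate any offset).  With only country-mean
opportunity costs available, participation is all-or-nothing: a country
sells its whole cap when the net credit price times the cap exceeds the
agricultural NPV of the threatened forest area, else nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .world import GridWorld, CountryTable, FOREST_CLASSES
from .allocation import AllocationResult, T_CROP_NEW

KM2_TO_HA = 100.0
#: Mass ratio CO2 : C, applied when forest carbon is given in Mg C ha⁻¹.
CO2_PER_C = 44.0 / 12.0


@dataclass
class ReddResult:
    table: pd.DataFrame   # rows: country × price

    def credits_at(self, price: float) -> pd.Series:
        sel = self.table[self.table["price"] == price]
        return sel.set_index("country")["credits_sold"]


def deforestation_rate(F2000: float, F2015: float, years: int = 15) -> float:
    """Projected annualized deforestation fraction, floored at zero."""
    if F2000 <= 0:
        raise ValueError("country has no 2000 forest; rate undefined")
    return max(0.0, (F2000 - F2015) / (years * F2000))


def credit_cap(D: float, D_b: float, area_co2e_by_type: dict) -> float:
    """Credit cap: above-baseline share of cropland-driven forest CO2e.

    ``area_co2e_by_type`` maps forest type k to (A_jk in ha, CO2e per
    ha).  Returns 0 when the projected rate does not exceed baseline.
    """
    if D <= D_b or D <= 0:
        return 0.0
    total = sum(a * co2 for a, co2 in area_co2e_by_type.values())
    return (D - D_b) / D * total


def participation(net_price: float, avoid: float, V: float, A_ha: float):
    """Bang-bang sale decision: all of the cap or none of it.

    The country sells iff credit revenue strictly exceeds the
    agricultural NPV of the threatened area (net_price·avoid > V·A).
    """
    if avoid <= 0:
        return False, 0.0
    if net_price * avoid > V * A_ha:
        return True, avoid
    return False, 0.0


def run_redd(world: GridWorld, alloc: AllocationResult, table: CountryTable,
             prices, years: int = 15, hdi_cutoff: float = 0.8,
             carbon_units: str = "C") -> ReddResult:
    """Country × price avoided-emission credits for one scenario.

    Forest-to-cropland areas A_jk are measured from the transition
    raster; per-type CO2e densities come from the country forest-carbon
    means (converted from Mg C with 44/12 when ``carbon_units == "C"``).
    Only developing countries (HDI below ``hdi_cutoff``; unclassified
    HDI treated as developing) can participate.
    """
    factor = CO2_PER_C if carbon_units == "C" else 1.0
    tr = alloc.transition
    rows = []
    for c in world.countries:
        in_c = world.country_id == c
        F2000 = float(world.cell_area[in_c & np.isin(world.lulc2000,
                                                     FOREST_CLASSES)].sum())
        F2015 = float(world.cell_area[in_c & np.isin(alloc.lulc2015,
                                                     FOREST_CLASSES)].sum())
        hdi = table.countries["hdi"].get(c, np.nan)
        developing = (not np.isfinite(hdi)) or hdi < hdi_cutoff
        D_b = float(table.countries["baseline_defor"].get(c, 0.0))
        V = float(table.countries["ag_npv"].get(c, 0.0))
        if F2000 <= 0:
            for p in prices:
                rows.append(_row(c, p, np.nan, D_b, False, 0.0, 0.0,
                                 False, 0.0))
            continue
        D = deforestation_rate(F2000, F2015, years)
        by_type = {}
        A_total = 0.0
        for k in FOREST_CLASSES:
            sel = in_c & (world.lulc2000 == k) & (tr == T_CROP_NEW)
            a_ha = float(world.cell_area[sel].sum()) * KM2_TO_HA
            co2 = float(table.countries[f"carbon_forest_{k}"].get(c, 0.0)) * factor
            by_type[k] = (a_ha, co2)
            A_total += a_ha
        eligible = developing and D > D_b
        avoid = credit_cap(D, D_b, by_type) if eligible else 0.0
        for p in prices:
            part, sold = participation(p, avoid, V, A_total) if eligible \
                else (False, 0.0)
            rows.append(_row(c, p, D, D_b, eligible, A_total, avoid,
                             part, sold))
    return ReddResult(table=pd.DataFrame(rows))


def _row(c, p, D, D_b, eligible, A_ha, avoid, part, sold):
    return {"country": c, "price": float(p), "D": D, "D_b": D_b,
            "eligible": eligible, "forest_to_crop_ha": A_ha,
            "avoid": avoid, "participates": part, "credits_sold": sold}
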