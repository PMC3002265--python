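"""Annual water yield via a Budyko-curve evapotranspiration fraction.

Water yield W = P·(1 − AET/P) is the precipitation left to surface and
ground water after actual evapotranspiration.  AET/P follows the
Zhang-style Budyko approximation (1 + ωR)/(1 + ωR + 1/R), with dryness
index R = k·ETo/P (k the land-cover evapotranspiration coefficient, ETo
reference evapotranspiration) and ω = Z·AWC/P the plant-accessible
water-storage ratio (Z a per-basin seasonality calibration constant,
AWC plant-available water content).  R > 1 flags potentially arid
cells.  Each climate epoch pairs with its land-cover map: the early
epoch with the 2000 map, the late epoch with a scenario's 2015 map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .world import GridWorld, CROPLAND
from .allocation import AllocationResult


@dataclass
class WaterYieldMap:
    W: np.ndarray        # mm yr⁻¹
    aet: np.ndarray      # mm yr⁻¹
    dryness: np.ndarray  # R, dimensionless; > 1 potentially arid
    omega: np.ndarray    # dimensionless
    epoch: str           # "e2000" | "e2015"


def dryness_index(eto, k, p):
    """Budyko dryness index R = k·ETo / P (potential ET over precipitation)."""
    eto = np.asarray(eto, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(p > 0, k * eto / p, np.nan)
    return r if r.ndim else float(r)

def budyko_omega(z, awc, p):
    """ω = Z·AWC / P, the linearized soil-water-storage ratio."""
    awc = np.asarray(awc, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(p > 0, z * awc / p, np.nan)
    return w if w.ndim else float(w)


def aet_fraction(omega, r):
    """Budyko-curve AET/P = (1 + ωR) / (1 + ωR + 1/R), in [0, 1).

    Monotone nondecreasing in both arguments; → 0 as R → 0
    (energy-limited) and → 1 as R → ∞ (water-limited).
    """
    omega = np.asarray(omega, dtype=float)
    r = np.asarray(r, dtype=float)
    wr = 1.0 + omega * r
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(r > 0, wr / (wr + 1.0 / r), 0.0)
        frac = np.where(np.isnan(omega) | np.isnan(r), np.nan, frac)
    return frac if frac.ndim else float(frac)


def water_yield_map(world: GridWorld, lulc: np.ndarray, epoch: str) -> WaterYieldMap:
    """Per-cell annual water yield for one climate epoch and LULC map."""
    if epoch == "e2000":
        p = world.precip_e1
    elif epoch == "e2015":
        p = world.precip_e2
    else:
        raise ValueError("epoch must be 'e2000' or 'e2015'")
    k = world.kcoef_map(lulc)
    z = world.zconst_map()
    r = dryness_index(world.eto, k, p)
    omega = budyko_omega(z, world.awc, p)
    frac = aet_fraction(omega, r)
    aet = p * frac
    return WaterYieldMap(W=p - aet, aet=aet, dryness=r, omega=omega, epoch=epoch)


def rainfed_summary(world: GridWorld, alloc: AllocationResult,
                    wy2000: WaterYieldMap, wy2015: WaterYieldMap) -> pd.DataFrame:
    """Country-level rainfed-cropland area and water-yield change.

    Rainfed cropland = cropland cells not assigned the irrigated
    potential yield.  Reports per country the percent change in rainfed
    cropland cell area and in mean annual water yield on 2015 rainfed
    cropland (late vs early epoch), plus the tension quadrant: the
    lower-right quadrant (area up, water down) marks countries whose
    projected rainfed expansion may be water-limited.
    """
    rainfed = ~alloc.irrigation.assigned_irrigated
    r2000 = (world.lulc2000 == CROPLAND) & rainfed
    r2015 = (alloc.lulc2015 == CROPLAND) & rainfed
    rows = []
    for c in world.countries:
        in_c = world.country_id == c
        a0 = float(world.cell_area[in_c & r2000].sum())
        a1 = float(world.cell_area[in_c & r2015].sum())
        sel = in_c & r2015
        if not sel.any():
            rows.append({"country": c, "present": False, "area2000": a0,
                         "area2015": a1, "area_change_pct": np.nan,
                         "w2000": np.nan, "w2015": np.nan,
                         "w_change_pct": np.nan, "quadrant": "absent"})
            continue
        wt = world.cell_area[sel]
        w0 = float(np.nansum(wy2000.W[sel] * wt) / wt.sum())
        w1 = float(np.nansum(wy2015.W[sel] * wt) / wt.sum())
        da = (a1 - a0) / a0 * 100.0 if a0 > 0 else np.nan
        dw = (w1 - w0) / w0 * 100.0 if w0 > 0 else np.nan
        quad = _quadrant(da, dw)
        rows.append({"country": c, "present": True, "area2000": a0,
                     "area2015": a1, "area_change_pct": da,
                     "w2000": w0, "w2015": w1, "w_change_pct": dw,
                     "quadrant": quad})
    return pd.DataFrame(rows).set_index("country")


def _quadrant(area_change_pct: float, w_change_pct: float) -> str:
    if not (np.isfinite(area_change_pct) and np.isfinite(w_change_pct)):
        return "undefined"
    horiz = "right" if area_change_pct >= 0 else "left"
    vert = "upper" if w_change_pct >= 0 else "lower"
    return f"{vert} {horiz}"


def global_rainfed_means(world: GridWorld, alloc: AllocationResult,
                         wy2000: WaterYieldMap, wy2015: WaterYieldMap) -> dict:
    """Area-weighted global mean W on rainfed cropland, both epochs."""
    rainfed = ~alloc.irrigation.assigned_irrigated
    out = {}
    for name, lulc, wy in (("w2000", world.lulc2000, wy2000),
                           ("w2015", alloc.lulc2015, wy2015)):
        sel = (lulc == CROPLAND) & rainfed & (world.country_id > 0)
        wt = world.cell_area[sel]
        out[name] = float(np.nansum(wy.W[sel] * wt) / wt.sum()) if sel.any() else np.nan
    return out
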