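"""Areal change targets and annual-step cellular allocation.

Targets: 2015 cropland grid-cell area per allocation unit is the 2000
area scaled by the unit's cropland growth rate, capped by arable area;
the change is decomposed into newly established cropland, retained
cropland, and abandoned cropland once the (ex-post measured) loss of
2000 cropland to urban use is known.

Allocation: change is placed on the grid in annual steps.  Expansion
converts the highest-suitability eligible cells adjacent (8-neighbour)
to the current extent of the land use; when the adjacent frontier runs
dry the adjacency constraint is relaxed for the remainder of that year's
quota.  Contraction removes the lowest-suitability cropland first and
relabels it with the ecoregion's dominant natural vegetation class.
Ties are broken by a seeded uniform draw, so a fixed seed reproduces the
allocation exactly.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .world import GridWorld, CountryTable, URBAN, CROPLAND, GRASSLAND
from .suitability import (SuitabilityMap, assign_irrigation,
                          cropland_suitability, urban_suitability)

# transition raster codes
T_UNCHANGED = 0
T_URBAN_NEW = 1
T_CROP_NEW = 2
T_CROP_RETAINED = 3
T_CROP_ABANDONED = 4

TRANSITION_NAMES = {
    T_UNCHANGED: "unchanged", T_URBAN_NEW: "urban_new",
    T_CROP_NEW: "crop_new", T_CROP_RETAINED: "crop_retained",
    T_CROP_ABANDONED: "crop_abandoned",
}

_EIGHT = np.ones((3, 3), dtype=bool)


class AllocationInfeasibleError(RuntimeError):
    """A unit's conversion target exceeds its eligible area."""


def cropland_target(C: float, g: float, arable: float) -> float:
    """2015 cropland grid-cell area: growth-scaled, capped by arable area."""
    if C < 0 or arable < 0:
        raise ValueError("areas must be non-negative")
    if g <= 0:
        raise ValueError("growth factor must be positive")
    return min(g * C, arable)


def decompose_cropland(C: float, C_prime: float, CU: float):
    """Split the 2015 cropland area into new, old and abandoned parts.

    With ``CU`` the 2000 cropland lost to urban use: under net expansion
    (C′ ≥ C − CU) the surviving 2000 cropland is all retained
    (C_old = C − CU) and the remainder is newly established; under net
    contraction nothing new is established (C_old = C′) and the excess
    surviving cropland is abandoned.
    """
    if min(C, C_prime, CU) < 0:
        raise ValueError("areas must be non-negative")
    if CU > C + 1e-9:
        raise ValueError("urbanized cropland exceeds 2000 cropland")
    surviving = C - CU
    if C_prime >= surviving:
        return C_prime - surviving, surviving, 0.0
    return 0.0, C_prime, surviving - C_prime


def _cells_for_area(target_area: float, cell_area: float) -> int:
    """Nearest-in-area cell count for an areal target."""
    t = target_area / cell_area
    n = int(np.floor(t))
    if t - n >= 0.5:
        n += 1
    return n


def allocate_expansion(lulc: np.ndarray, suit: SuitabilityMap,
                       cell_area: np.ndarray, target_area: float,
                       landuse: int, years: int, seed: int,
                       unit_mask: np.ndarray | None = None) -> np.ndarray:
    """Convert cells to *landuse* until the areal target is met.

    Annual quotas (target/years cells with carried remainder) are filled
    by repeatedly converting the best eligible cell on the 8-neighbour
    frontier of the current extent, re-evaluating the frontier after
    every conversion; if the frontier empties, any eligible cell may
    convert for the rest of that year.  Units with no existing extent of
    the land use waive the proximity constraint entirely.  Returns the
    boolean mask of converted cells.
    """
    shape = lulc.shape
    if unit_mask is None:
        unit_mask = np.ones(shape, dtype=bool)
    extent = (lulc == landuse) & unit_mask
    eligible = suit.eligible & unit_mask & ~extent
    ca = float(cell_area[unit_mask].mean()) if unit_mask.any() else 1.0
    n = _cells_for_area(target_area, ca)
    if n == 0:
        return np.zeros(shape, dtype=bool)
    if n > int(eligible.sum()):
        raise AllocationInfeasibleError(
            f"target of {n} cells exceeds {int(eligible.sum())} eligible "
            f"cells for land use {landuse}")

    rng = np.random.default_rng(seed)
    # tie-break jitter, far below the 12.5-point score granularity
    prio = np.where(np.isfinite(suit.score), suit.score, -np.inf) \
        + rng.random(shape) * 1e-6
    converted = np.zeros(shape, dtype=bool)
    in_heap = np.zeros(shape, dtype=bool)
    heap: list = []
    nrow, ncol = shape

    def push(r, c):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (0 <= rr < nrow and 0 <= cc < ncol
                        and eligible[rr, cc] and not converted[rr, cc]
                        and not in_heap[rr, cc]):
                    heapq.heappush(heap, (-prio[rr, cc], rr, cc))
                    in_heap[rr, cc] = True

    waive_proximity = not extent.any()
    if not waive_proximity:
        frontier = eligible & ndimage.binary_dilation(extent, _EIGHT)
        for r, c in zip(*np.nonzero(frontier)):
            heapq.heappush(heap, (-prio[r, c], int(r), int(c)))
            in_heap[r, c] = True

    acc, allocated = 0.0, 0
    for _ in range(int(years)):
        acc += n / years
        quota = int(np.floor(acc + 1e-9)) - allocated
        relaxed = waive_proximity
        for _ in range(quota):
            pick = None
            if not relaxed:
                while heap:
                    _, r, c = heapq.heappop(heap)
                    in_heap[r, c] = False
                    if eligible[r, c] and not converted[r, c]:
                        pick = (r, c)
                        break
                if pick is None:
                    relaxed = True
            if pick is None:
                # adjacency relaxed: best eligible cell anywhere in unit
                cand = eligible & ~converted
                if not cand.any():
                    raise AllocationInfeasibleError(
                        "eligible cells exhausted mid-allocation")
                flat = np.where(cand.ravel(), prio.ravel(), -np.inf)
                pick = np.unravel_index(int(np.argmax(flat)), shape)
            r, c = pick
            converted[r, c] = True
            allocated += 1
            push(r, c)
    return converted


def allocate_contraction(lulc: np.ndarray, score: np.ndarray,
                         cell_area: np.ndarray, loss_area: float,
                         seed: int, unit_mask: np.ndarray | None = None,
                         exclude: np.ndarray | None = None) -> np.ndarray:
    """Abandon the lowest-suitability cropland cells for an areal loss.

    Returns the boolean mask of abandoned cells (callers relabel them to
    the ecoregion's natural vegetation class).
    """
    shape = lulc.shape
    if unit_mask is None:
        unit_mask = np.ones(shape, dtype=bool)
    pool = (lulc == CROPLAND) & unit_mask
    if exclude is not None:
        pool &= ~exclude
    ca = float(cell_area[unit_mask].mean()) if unit_mask.any() else 1.0
    n = _cells_for_area(loss_area, ca)
    if n == 0:
        return np.zeros(shape, dtype=bool)
    if n > int(pool.sum()):
        raise AllocationInfeasibleError(
            f"loss of {n} cells exceeds {int(pool.sum())} removable "
            f"cropland cells")
    rng = np.random.default_rng(seed)
    prio = np.where(np.isfinite(score), score, np.inf) + rng.random(shape) * 1e-6
    flat_idx = np.nonzero(pool.ravel())[0]
    order = flat_idx[np.argsort(prio.ravel()[flat_idx], kind="stable")]
    out = np.zeros(shape, dtype=bool)
    out.ravel()[order[:n]] = True
    return out


def dominant_natural_class(lulc2000: np.ndarray, ecoregion_id: np.ndarray) -> dict:
    """Modal non-urban, non-cropland 2000 class per ecoregion.

    Ecoregions with no natural land fall back to grassland.
    """
    out = {}
    for e in np.unique(ecoregion_id[ecoregion_id > 0]):
        sel = (ecoregion_id == e) & (lulc2000 != URBAN) & (lulc2000 != CROPLAND)
        if sel.any():
            vals, counts = np.unique(lulc2000[sel], return_counts=True)
            out[int(e)] = int(vals[np.argmax(counts)])
        else:
            out[int(e)] = GRASSLAND
    return out


@dataclass
class AllocationResult:
    """2015 land-cover map, per-cell transition labels, realized areas."""

    lulc2015: np.ndarray
    transition: np.ndarray
    targets: pd.DataFrame           # per allocation unit
    urban_new: np.ndarray           # bool mask (identical across scenarios)
    crop_suitability: SuitabilityMap
    irrigation: "object"            # IrrigationAssignment


def run_allocation(world: GridWorld, table: CountryTable, config) -> AllocationResult:
    """Allocate 2000→2015 urban then cropland change for one scenario.

    Urbanization is always allocated per country (the urban pattern is
    shared by both scenarios); cropland targets are then computed and
    allocated per country or per region according to
    ``config.allocation_unit``, using the realized cropland-to-urban
    conversion in the decomposition.
    """
    years = config.years
    lulc = world.lulc2000.copy()
    urb_suit = urban_suitability(world)
    urban_new = np.zeros(world.shape, dtype=bool)

    dU = table.delta_urban
    for c in world.countries:
        target = float(dU.get(c, 0.0))
        if target <= 0:
            continue
        conv = allocate_expansion(lulc, urb_suit, world.cell_area, target,
                                  URBAN, years, seed=_unit_seed(config.seed, 1, c),
                                  unit_mask=world.country_id == c)
        lulc[conv] = URBAN
        urban_new |= conv

    assignment = assign_irrigation(world, config.irrigation_strictness,
                                   config.irrigation_threshold)
    unit_kind = "country" if config.allocation_unit == "country" else "region"
    crop_suit = cropland_suitability(world, assignment, unit=unit_kind,
                                     urban2015_new=urban_new)
    unit_ids = world.country_id if unit_kind == "country" else world.region_id
    rates = (table.countries["crop_rate"] if unit_kind == "country"
             else table.regions["crop_rate"])

    eco_class = dominant_natural_class(world.lulc2000, world.ecoregion_id)
    crop2000 = world.lulc2000 == CROPLAND
    rows = []
    for u in np.unique(unit_ids[unit_ids > 0]):
        u = int(u)
        mask = unit_ids == u
        C = world.class_area(world.lulc2000, CROPLAND, mask)
        arable_now = (world.arable & ~world.protected
                      & (world.lulc2000 != URBAN) & ~urban_new & mask)
        A = float(world.cell_area[arable_now].sum())
        CU = float(world.cell_area[crop2000 & urban_new & mask].sum())
        g = float(rates.get(u, 1.0))
        Cp = cropland_target(C, g, A)
        C_new, C_old, abandoned = decompose_cropland(C, Cp, CU)
        if C_new > 0:
            conv = allocate_expansion(lulc, crop_suit, world.cell_area, C_new,
                                      CROPLAND, years,
                                      seed=_unit_seed(config.seed, 2, u),
                                      unit_mask=mask)
            lulc[conv] = CROPLAND
        if abandoned > 0:
            ab = allocate_contraction(lulc, crop_suit.score, world.cell_area,
                                      abandoned,
                                      seed=_unit_seed(config.seed, 3, u),
                                      unit_mask=mask, exclude=urban_new)
            for e, cls in eco_class.items():
                sel = ab & (world.ecoregion_id == e)
                lulc[sel] = cls
        rows.append({"unit": u, "C": C, "C_prime": Cp, "CU": CU,
                     "C_new": C_new, "C_old": C_old, "abandoned": abandoned,
                     "delta_urban": float(
                         world.cell_area[urban_new & mask].sum())})
    targets = pd.DataFrame(rows).set_index("unit")

    transition = np.full(world.shape, T_UNCHANGED, dtype=np.int32)
    transition[urban_new] = T_URBAN_NEW
    crop_new = (lulc == CROPLAND) & ~crop2000
    transition[crop_new] = T_CROP_NEW
    transition[crop2000 & (lulc == CROPLAND)] = T_CROP_RETAINED
    transition[crop2000 & (lulc != CROPLAND) & ~urban_new] = T_CROP_ABANDONED
    targets["realized_crop_new"] = [
        float(world.cell_area[(transition == T_CROP_NEW) & (unit_ids == u)].sum())
        for u in targets.index]
    return AllocationResult(lulc2015=lulc, transition=transition,
                            targets=targets, urban_new=urban_new,
                            crop_suitability=crop_suit, irrigation=assignment)


def _unit_seed(base: int, stage: int, unit: int) -> int:
    """Deterministic per-stage, per-unit child seed."""
    return int(np.random.SeedSequence([base, stage, unit])
               .generate_state(1)[0] % (2 ** 31))
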