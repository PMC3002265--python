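"""End-to-end scenario runs and the run-directory layout.

``run_scenario`` executes the full chain — urban then cropland
allocation, harvested-area and production accounting, water yield on
both climate epochs, carbon stock change, REDD crediting, and the
report summaries — and ``write_run`` persists it as::

    run_dir/
      inputs/manifest.json      # seed + input hashes, for reruns
      suitability/*.tif
      lulc_2015.tif, transitions.tif
      wateryield_2000.tif, wateryield_2015.tif
      carbon_2000.tif, carbon_2015.tif
      tables/*.csv
      report.json
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .world import GridWorld, CountryTable, CropGroupTable, CROPLAND, URBAN
from .config import ScenarioConfig
from .allocation import run_allocation, AllocationResult, T_CROP_NEW
from .agriculture import (harvest_areas, suitability_inflators,
                          production_2015, HarvestAreas, ProductionResult)
from .water_yield import (water_yield_map, rainfed_summary,
                          global_rainfed_means, WaterYieldMap)
from .carbon import carbon_delta, mean_storage_by_class, CarbonResult
from .redd import run_redd, ReddResult
from .reporting import (hdi_curves, ecoregion_undeveloped_change,
                        undeveloped_change, tradeoff_ratios, render_figures,
                        ScenarioReport)
from .suitability import urban_suitability
from . import raster


@dataclass
class ScenarioRun:
    """Everything one scenario run produced, in memory."""

    config: ScenarioConfig
    world: GridWorld
    table: CountryTable
    crops: CropGroupTable
    allocation: AllocationResult
    harvest: HarvestAreas
    production: ProductionResult
    wy2000: WaterYieldMap
    wy2015: WaterYieldMap
    rainfed: pd.DataFrame
    carbon: CarbonResult
    redd: ReddResult
    report: ScenarioReport


def run_scenario(world: GridWorld, table: CountryTable,
                 crops: CropGroupTable, config: ScenarioConfig) -> ScenarioRun:
    alloc = run_allocation(world, table, config)
    harvest = harvest_areas(world, alloc, table.countries)
    inflators = suitability_inflators(world, alloc)
    production = production_2015(harvest, crops, inflators,
                                 q=config.crop_mix_id,
                                 delta=config.delta_readiness)
    wy2000 = water_yield_map(world, world.lulc2000, "e2000")
    wy2015 = water_yield_map(world, alloc.lulc2015, "e2015")
    rainfed = rainfed_summary(world, alloc, wy2000, wy2015)
    means = mean_storage_by_class(world.carbon2000, world.lulc2000,
                                  world.country_id, world.cell_area)
    carbon = carbon_delta(world, alloc, means)
    redd = run_redd(world, alloc, table, config.credit_prices,
                    years=config.years,
                    hdi_cutoff=config.hdi_developing_cutoff)
    report = build_report(world, table, alloc, harvest, production,
                          carbon, redd, config)
    return ScenarioRun(config=config, world=world, table=table, crops=crops,
                       allocation=alloc, harvest=harvest,
                       production=production, wy2000=wy2000, wy2015=wy2015,
                       rainfed=rainfed, carbon=carbon, redd=redd,
                       report=report)


def build_report(world, table, alloc, harvest, production, carbon, redd,
                 config) -> ScenarioReport:
    """HDI-sorted cumulative curves plus global summary quantities."""
    cid = world.country_id
    ctotals = production.country_totals()
    metrics = pd.DataFrame(index=table.countries.index)
    metrics["urban_area_change"] = [
        float(world.cell_area[alloc.urban_new & (cid == c)].sum())
        for c in metrics.index]
    metrics["cropland_area_change"] = [
        float(world.cell_area[(alloc.lulc2015 == CROPLAND) & (cid == c)].sum())
        - float(world.cell_area[(world.lulc2000 == CROPLAND) & (cid == c)].sum())
        for c in metrics.index]
    metrics["harvested_area_change"] = (harvest.table["H2015"]
                                        - harvest.table["H2000"])
    metrics["mass_change"] = ctotals["mass2015"] - ctotals["mass2000"]
    metrics["calorie_change"] = ctotals["cal2015"] - ctotals["cal2000"]
    metrics["carbon_delta"] = carbon.table["delta"]
    top_price = max(config.credit_prices)
    metrics["credits"] = redd.credits_at(top_price).reindex(metrics.index)
    curves, unclassified = hdi_curves(metrics.fillna(0.0),
                                      table.countries["hdi"])

    eco = ecoregion_undeveloped_change(
        world, alloc,
        endangered_fraction=None if table.ecoregions is None
        else table.ecoregions["endangered_fraction"])
    undev = undeveloped_change(world, alloc)
    gtot = production.global_totals()
    summary = {
        "scenario": config.scenario_name,
        "allocation_unit": config.allocation_unit,
        "urban_area_change_km2": float(metrics["urban_area_change"].sum()),
        "cropland_area_change_km2": float(metrics["cropland_area_change"].sum()),
        "mass2000_mg": float(gtot["mass2000"]),
        "mass2015_mg": float(gtot["mass2015"]),
        "cal2000": float(gtot["cal2000"]),
        "cal2015": float(gtot["cal2015"]),
        "carbon_delta_mg": float(carbon.table["delta"].sum()),
        "undeveloped_gross_loss_km2": undev["gross_loss"],
        "undeveloped_net_change_km2": undev["net_change"],
        "credits_by_price": {
            str(p): float(redd.credits_at(p).sum())
            for p in config.credit_prices},
    }
    delta_cal = summary["cal2015"] - summary["cal2000"]
    tradeoffs = {}
    if delta_cal > 0:
        tradeoffs = tradeoff_ratios(summary["carbon_delta_mg"], delta_cal,
                                    summary["undeveloped_net_change_km2"])
    return ScenarioReport(hdi_curves=curves, unclassified_totals=unclassified,
                          ecoregion_table=eco, tradeoffs=tradeoffs,
                          summary=summary)


def write_run(run: ScenarioRun, out_dir) -> Path:
    """Persist a scenario run to disk in the standard layout."""
    out = Path(out_dir)
    for sub in ("inputs", "suitability", "tables"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    world = run.world
    ca = float(world.cell_area.mean())

    raster.write_raster(run.allocation.lulc2015, out / "lulc_2015.tif", ca)
    raster.write_raster(run.allocation.transition, out / "transitions.tif", ca)
    urb = urban_suitability(world)
    raster.write_raster(urb.masked_score(), out / "suitability" / "urban.tif", ca)
    raster.write_raster(run.allocation.crop_suitability.masked_score(),
                        out / "suitability" / "cropland.tif", ca)
    raster.write_raster(run.allocation.irrigation.assigned_irrigated,
                        out / "suitability" / "irrigated_mask.tif", ca)
    raster.write_raster(run.wy2000.W, out / "wateryield_2000.tif", ca)
    raster.write_raster(run.wy2015.W, out / "wateryield_2015.tif", ca)
    raster.write_raster(run.carbon.storage2000, out / "carbon_2000.tif", ca)
    raster.write_raster(run.carbon.storage2015, out / "carbon_2015.tif", ca)

    raster.write_table(run.allocation.targets.reset_index(),
                       out / "tables" / "areal_targets.csv")
    raster.write_table(run.harvest.table.reset_index(),
                       out / "tables" / "harvested_area.csv")
    prod = run.production.table.reset_index()
    prod.insert(2, "q", run.config.crop_mix_id)
    raster.write_table(prod, out / "tables" / "production_by_country.csv")
    raster.write_table(run.rainfed.reset_index(),
                       out / "tables" / "rainfed_water.csv")
    raster.write_table(run.carbon.table.reset_index(),
                       out / "tables" / "carbon_delta_by_country.csv")
    raster.write_table(run.redd.table, out / "tables" / "redd_by_country.csv")
    raster.write_table(run.report.hdi_curves.reset_index(),
                       out / "tables" / "hdi_curves.csv")
    raster.write_table(run.report.ecoregion_table.reset_index(),
                       out / "tables" / "ecoregions.csv")

    report = {"summary": run.report.summary,
              "tradeoffs": run.report.tradeoffs,
              "unclassified_hdi_totals":
                  run.report.unclassified_totals.to_dict()}
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "inputs" / "manifest.json").write_text(
        json.dumps(manifest(run.world, run.config), indent=2))
    render_figures(run.report, run.rainfed, out / "figures")

    tg = run.allocation.targets
    lines = [f"scenario: {run.config.scenario_name}",
             f"allocation_unit: {run.config.allocation_unit}",
             f"seed: {run.config.seed}",
             f"world: {run.world.shape[0]}x{run.world.shape[1]}, "
             f"{len(run.world.countries)} countries"]
    for u, row in tg.iterrows():
        lines.append(
            f"unit {u}: C={row['C']:.1f} C'={row['C_prime']:.1f} "
            f"new={row['C_new']:.1f} abandoned={row['abandoned']:.1f} "
            f"dU={row['delta_urban']:.1f}")
    (out / "log.txt").write_text("\n".join(lines) + "\n")
    return out


def manifest(world: GridWorld, config: ScenarioConfig) -> dict:
    """Input hashes plus the seed: identical manifest ⇒ identical outputs."""
    h = {}
    for name in ("lulc2000", "slope", "popdens2015", "yield_rainfed",
                 "yield_irrigated", "irrig2000", "precip_e1", "precip_e2",
                 "eto", "awc", "carbon2000", "protected", "arable",
                 "country_id", "region_id", "ecoregion_id", "basin_id",
                 "cropzone", "cell_area"):
        arr = np.ascontiguousarray(getattr(world, name))
        h[name] = hashlib.sha256(arr.tobytes()).hexdigest()[:16]
    return {"seed": config.seed, "config": config.to_dict(),
            "input_hashes": h}
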