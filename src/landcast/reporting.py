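"""Scenario summaries: HDI-sorted cumulative curves, ecoregion
undeveloped-land accounting, net-change decomposition, tradeoff ratios.

Country-level outcomes are presented as cumulative series over
countries sorted by ascending HDI, which shows how much of a global
change accrues below any development level; countries without an HDI
are excluded from the curve and totalled separately.  "Undeveloped
land" — every class except urban and cropland — is the habitat proxy;
its gross loss ignores cropland abandonment while its net change
credits it.  The headline cross-scenario comparison is grams of biomass
carbon emitted, and m² of undeveloped land lost, per additional calorie
of crop production.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .world import GridWorld, URBAN, CROPLAND
from .allocation import (AllocationResult, T_URBAN_NEW, T_CROP_NEW,
                         T_CROP_ABANDONED)


@dataclass
class ScenarioReport:
    hdi_curves: pd.DataFrame          # one column per metric, cumulative
    unclassified_totals: pd.Series    # same metrics, HDI-less countries
    ecoregion_table: pd.DataFrame
    tradeoffs: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def hdi_cumulative(values: pd.Series, hdi: pd.Series) -> tuple[pd.Series, float]:
    """Cumulative sum over countries sorted by ascending HDI.

    Returns (series indexed by country in HDI order, total over
    countries with no HDI classification, which are excluded from the
    curve).
    """
    values = values.astype(float)
    classified = hdi[np.isfinite(hdi)].sort_values(kind="stable")
    curve = values.reindex(classified.index).fillna(0.0).cumsum()
    unclassified = float(values.reindex(hdi.index[~np.isfinite(hdi)])
                         .fillna(0.0).sum())
    return curve, unclassified


def hdi_curves(metrics: pd.DataFrame, hdi: pd.Series):
    """Apply :func:`hdi_cumulative` to every metric column."""
    curves = {}
    extra = {}
    for col in metrics.columns:
        curves[col], extra[col] = hdi_cumulative(metrics[col], hdi)
    return pd.DataFrame(curves), pd.Series(extra)


def ecoregion_undeveloped_change(world: GridWorld, alloc: AllocationResult,
                                 endangered_fraction: pd.Series | None = None,
                                 include_classes=None) -> pd.DataFrame:
    """Gross and net undeveloped-land change per ecoregion (km²).

    Gross loss counts undeveloped cells converting to urban or cropland
    and deliberately ignores gains from cropland abandonment; net change
    credits the abandonment.  If an endangered-species fraction per
    ecoregion is supplied, ecoregions are placed in risk quadrants
    (loss vs species exposure) using the medians as axes.
    """
    tr = alloc.transition
    undeveloped_lost = np.isin(tr, [T_URBAN_NEW, T_CROP_NEW]) \
        & (world.lulc2000 != URBAN) & (world.lulc2000 != CROPLAND)
    if include_classes is not None:
        undeveloped_lost &= np.isin(world.lulc2000, include_classes)
    gained = tr == T_CROP_ABANDONED
    rows = []
    for e in np.unique(world.ecoregion_id[world.ecoregion_id > 0]):
        sel = world.ecoregion_id == e
        gross = float(world.cell_area[sel & undeveloped_lost].sum())
        gain = float(world.cell_area[sel & gained].sum())
        rows.append({"ecoregion": int(e), "gross_loss": gross,
                     "abandonment_gain": gain, "net_change": gain - gross})
    df = pd.DataFrame(rows).set_index("ecoregion")
    if endangered_fraction is not None:
        df["endangered_fraction"] = endangered_fraction.reindex(df.index)
        loss_med = df["gross_loss"].median()
        sp_med = df["endangered_fraction"].median()
        df["quadrant"] = [
            f"{'high' if l >= loss_med else 'low'}_loss_"
            f"{'high' if s >= sp_med else 'low'}_species"
            for l, s in zip(df["gross_loss"], df["endangered_fraction"])]
    return df


def net_change_decomposition(gross_to_class: float, class_to_urban: float,
                             class_to_other: float) -> float:
    """Net areal change of a class from its gross gain and losses."""
    return gross_to_class - class_to_urban - class_to_other


def tradeoff_ratios(delta_carbon_mg: float, delta_calories: float,
                    delta_undeveloped_km2: float) -> dict:
    """Emission and habitat-loss intensity of the caloric gain.

    Returns grams of biomass carbon released per additional calorie and
    m² of undeveloped land lost per additional calorie (losses positive).
    """
    if delta_calories <= 0:
        raise ValueError("tradeoff ratios require a positive caloric gain")
    return {
        "carbon_g_per_cal": -delta_carbon_mg * 1e6 / delta_calories,
        "habitat_m2_per_cal": -delta_undeveloped_km2 * 1e6 / delta_calories,
    }


def percent_reduction(ratio_low: float, ratio_high: float) -> float:
    """How much smaller the low scenario's ratio is, in percent of the high."""
    if ratio_high == 0:
        raise ValueError("reference ratio is zero")
    return (ratio_high - ratio_low) / ratio_high * 100.0


def render_figures(report: ScenarioReport, rainfed: pd.DataFrame,
                   out_dir) -> list:
    """Render the report's standard figures as PNG files.

    The tables are the analysis surface; these are the matching visual
    summaries: HDI-sorted cumulative curves, the rainfed-cropland
    water/area quadrant scatter, and ecoregion undeveloped-land change.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    curves = report.hdi_curves
    ncol = 3
    nrow = -(-len(curves.columns) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                             squeeze=False)
    for ax, col in zip(axes.ravel(), curves.columns):
        ax.plot(range(1, len(curves) + 1), curves[col], marker="o", ms=3)
        ax.set_title(col, fontsize=9)
        ax.set_xlabel("countries, ascending HDI")
    for ax in axes.ravel()[len(curves.columns):]:
        ax.axis("off")
    fig.tight_layout()
    p = out / "hdi_curves.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)

    present = rainfed[rainfed.get("present", pd.Series(dtype=bool)) == True]  # noqa: E712
    fig, ax = plt.subplots(figsize=(5, 4))
    if len(present):
        ax.scatter(present["area_change_pct"], present["w_change_pct"])
        for c, row in present.iterrows():
            ax.annotate(str(c), (row["area_change_pct"],
                                 row["w_change_pct"]), fontsize=8)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("rainfed cropland area change (%)")
    ax.set_ylabel("water yield change on rainfed cropland (%)")
    fig.tight_layout()
    p = out / "rainfed_quadrants.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)

    eco = report.ecoregion_table
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(eco.index.astype(str), eco["gross_loss"], label="gross loss")
    ax.bar(eco.index.astype(str), eco["net_change"], alpha=0.6,
           label="net change")
    ax.set_xlabel("ecoregion")
    ax.set_ylabel("undeveloped land change (km²)")
    ax.legend()
    fig.tight_layout()
    p = out / "ecoregions.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)
    return written


def undeveloped_change(world: GridWorld, alloc: AllocationResult) -> dict:
    """Global gross/net undeveloped-land change (km²), all ecoregions."""
    eco = ecoregion_undeveloped_change(world, alloc)
    return {"gross_loss": float(eco["gross_loss"].sum()),
            "net_change": float(eco["net_change"].sum())}
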