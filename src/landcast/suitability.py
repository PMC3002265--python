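"""Urban and cropland suitability scoring (0–100) with eligibility masks.

Urban suitability averages a 1–5 slope score with a 1–5 projected
population-density score; cropland suitability averages the slope score
with a 1–5 potential-cereal-yield score, where the per-cell potential
yield is first chosen between its rainfed and irrigated variant by a
similarity rule against cells that were highly irrigated in 2000.  The
1–5 average is rescaled affinely to 0–100.  Density and yield bins are
equal-interval within the allocation unit (country or region), so scores
are comparable only within a unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .world import GridWorld, URBAN, WATER, CROPLAND


@dataclass
class SuitabilityMap:
    """Per-cell 0–100 score plus the mask of cells open to conversion.

    ``score`` is defined (non-NaN) on every scored cell of the unit —
    including cells already in the target use, whose scores feed the
    land-quality inflators — while ``eligible`` marks only the cells a
    new conversion may claim.  :meth:`masked_score` gives the raster view
    with nodata outside the eligible mask.
    """

    score: np.ndarray
    eligible: np.ndarray
    landuse: str          # "urban" | "cropland"
    unit: str             # "country" | "region"

    def masked_score(self) -> np.ndarray:
        out = np.where(self.eligible, self.score, np.nan)
        return out


@dataclass
class IrrigationAssignment:
    """Chosen per-cell potential yield and the irrigated-choice mask."""

    potential_yield: np.ndarray
    assigned_irrigated: np.ndarray


def slope_score(slope) -> np.ndarray:
    """1–5 terrain score: flatter is better.

    <12% → 5, [12,18) → 4, [18,30) → 3, [30,50) → 2, ≥50% → 1.
    Lower bin edges are inclusive.
    """
    s = np.asarray(slope, dtype=float)
    if np.any(s[np.isfinite(s)] < 0):
        raise ValueError("negative slope")
    out = np.select([s < 12, s < 18, s < 30, s < 50], [5, 4, 3, 2], default=1)
    return out.astype(float) if out.ndim else float(out)


def popdensity_score(density, unit_max=None) -> np.ndarray:
    """1–5 projected-density score within one normalization unit.

    Zero density scores 1.  Positive densities are split into four
    equal-width right-closed bins anchored at zero, (0, m/4], (m/4, m/2],
    (m/2, 3m/4], (3m/4, m] with m the unit's maximum, mapped to 2–5.
    An all-zero unit scores 1 everywhere.
    """
    d = np.asarray(density, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    if np.any(d[np.isfinite(d)] < 0):
        raise ValueError("negative population density")
    if unit_max is None:
        pos = d[np.isfinite(d) & (d > 0)]
        unit_max = pos.max() if pos.size else 0.0
    out = np.ones_like(d)
    if unit_max > 0:
        pos = d > 0
        # right-closed bins: ceil(d * 4 / m) ∈ {1..4} → scores 2..5
        binno = np.ceil(d[pos] * 4.0 / unit_max)
        out[pos] = np.clip(binno, 1, 4) + 1
    return float(out[0]) if scalar else out


def yield_score(potential_yield, unit_min=None, unit_max=None) -> np.ndarray:
    """1–5 potential-yield score, equal intervals over the unit's range.

    Five equal-width bins over [min, max] with inclusive lower edges; a
    unit with constant yield scores 3 everywhere (midpoint convention).
    """
    y = np.asarray(potential_yield, dtype=float)
    scalar = y.ndim == 0
    y = np.atleast_1d(y)
    finite = np.isfinite(y)
    if unit_min is None:
        unit_min = y[finite].min() if finite.any() else 0.0
    if unit_max is None:
        unit_max = y[finite].max() if finite.any() else 0.0
    out = np.full_like(y, np.nan)
    if unit_max - unit_min <= 0:
        out[finite] = 3.0
    else:
        frac = (y[finite] - unit_min) / (unit_max - unit_min)
        out[finite] = np.clip(1 + np.floor(frac * 5.0), 1, 5)
    return float(out[0]) if scalar else out


def _rescale(avg_1_5: np.ndarray) -> np.ndarray:
    """Affine map of the 1–5 average onto the 0–100 scale."""
    return (avg_1_5 - 1.0) / 4.0 * 100.0


def assign_irrigation(world: GridWorld, strictness: float = 2.0,
                      threshold: float = 0.10) -> IrrigationAssignment:
    """Choose rainfed vs irrigated potential yield per cell, per country.

    Cells whose (rainfed, irrigated) potential-yield pair lies within
    Mahalanobis distance ``strictness`` of the centroid of the country's
    highly-irrigated cells (2000 irrigation fraction ≥ ``threshold``)
    take the irrigated yield; the highly-irrigated reference cells
    themselves always do.  Countries with no reference cells stay
    rainfed.  When the reference set is smaller than 5 cells the distance
    falls back to per-feature-scaled Euclidean.  Larger ``strictness``
    assigns weakly more cells their irrigated yield.
    """
    if strictness <= 0:
        raise ValueError("strictness must be positive")
    assigned = np.zeros(world.shape, dtype=bool)
    feats = np.stack([world.yield_rainfed, world.yield_irrigated], axis=-1)
    for c in world.countries:
        in_c = world.country_id == c
        ref = in_c & (world.irrig2000 >= threshold)
        if not ref.any():
            continue
        X = feats[ref]
        ok = np.isfinite(X).all(axis=1)
        X = X[ok]
        if X.shape[0] == 0:
            continue
        mu = X.mean(axis=0)
        cand = in_c & np.isfinite(feats).all(axis=-1)
        D = feats[cand] - mu
        if X.shape[0] >= 5:
            cov = np.cov(X, rowvar=False)
            # ridge keeps near-degenerate reference clouds invertible
            cov = cov + np.eye(2) * (1e-9 * max(np.trace(cov), 1.0))
            vi = np.linalg.inv(cov)
            d2 = np.einsum("ij,jk,ik->i", D, vi, D)
        else:
            sd = X.std(axis=0, ddof=0)
            # degenerate reference cloud: fall back to a tight 5% scale
            sd[sd <= 0] = 0.05 * max(np.abs(mu).max(), 1.0)
            d2 = ((D / sd) ** 2).sum(axis=1)
        close = np.zeros(world.shape, dtype=bool)
        close[cand] = d2 <= strictness ** 2
        assigned |= close | ref
    potential = np.where(assigned, world.yield_irrigated, world.yield_rainfed)
    return IrrigationAssignment(potential_yield=potential,
                                assigned_irrigated=assigned)


def urban_suitability(world: GridWorld) -> SuitabilityMap:
    """0–100 urban suitability: mean of slope and density scores.

    Density bins are normalized within each country.  Cells that are
    protected, water, outside any country, or already urban are not
    eligible for new urban land.
    """
    score = np.full(world.shape, np.nan)
    sl = slope_score(np.nan_to_num(world.slope, nan=0.0))
    for c in world.countries:
        in_c = world.country_id == c
        dens = world.popdens2015[in_c]
        pos = dens[np.isfinite(dens) & (dens > 0)]
        m = pos.max() if pos.size else 0.0
        ps = popdensity_score(np.nan_to_num(dens, nan=0.0), unit_max=m)
        score[in_c] = _rescale((sl[in_c] + ps) / 2.0)
    eligible = ((world.country_id > 0) & ~world.protected
                & (world.lulc2000 != WATER) & (world.lulc2000 != URBAN)
                & np.isfinite(score))
    return SuitabilityMap(score=score, eligible=eligible,
                          landuse="urban", unit="country")


def cropland_suitability(world: GridWorld, assignment: IrrigationAssignment,
                         unit: str = "country",
                         urban2015_new: np.ndarray | None = None) -> SuitabilityMap:
    """0–100 cropland suitability: mean of slope and potential-yield scores.

    The 1–5 yield bins are equal intervals over the allocation unit's
    arable yield range (country for the *country* scenario, region for
    the *regional* scenario).  Eligible cells for cropland expansion are
    arable, unprotected, not urban in 2000 or 2015, and not already
    cropland.
    """
    if unit not in ("country", "region"):
        raise ValueError("unit must be 'country' or 'region'")
    unit_ids = world.country_id if unit == "country" else world.region_id
    score = np.full(world.shape, np.nan)
    sl = slope_score(np.nan_to_num(world.slope, nan=0.0))
    py = assignment.potential_yield
    for u in np.unique(unit_ids[unit_ids > 0]):
        in_u = unit_ids == u
        dom = in_u & np.isfinite(py)
        ref = dom & world.arable
        vals = py[ref if ref.any() else dom]
        lo, hi = (vals.min(), vals.max()) if vals.size else (0.0, 0.0)
        ys = yield_score(py[dom], unit_min=lo, unit_max=hi)
        score[dom] = _rescale((sl[dom] + ys) / 2.0)
    eligible = (world.arable & ~world.protected
                & (world.lulc2000 != URBAN) & (world.lulc2000 != CROPLAND)
                & (world.lulc2000 != WATER) & (unit_ids > 0)
                & np.isfinite(score))
    if urban2015_new is not None:
        eligible &= ~urban2015_new
    return SuitabilityMap(score=score, eligible=eligible,
                          landuse="cropland",
                          unit=unit if unit == "country" else "region")
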