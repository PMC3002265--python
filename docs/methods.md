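# Methods

## Scope and assumptions

`landcast` models net 2000→2015 change in exactly two land uses —
urban and cropland — on a co-registered raster stack, and the
consequences of that change for crop output, water yield, biomass
carbon and avoided-deforestation credit supply.  Everything else is
held fixed: there is no pasture/rangeland dynamic, no transitions among
natural classes, no climate feedback on yields, and no within-period
carbon flux on unchanged cells.  Gross change is modelled only to the
extent needed to realize net change, so the engine understates the
total amount and variety of land turnover; the net-change
decomposition helper quantifies exactly what such an accounting misses.

Urbanization is allocated first and identically for both cropland
scenarios, so urban development outbids cropland on land suitable for
both, and cross-scenario differences are attributable to cropland
patterns alone.

## Suitability scoring

Both suitability layers average two 1–5 scores and rescale affinely to
0–100 via (avg − 1)/4 × 100 (order-preserving, so ranking is decided
on the 1–5 scale).

* **Slope score**: <12% → 5, [12, 18) → 4, [18, 30) → 3, [30, 50) → 2,
  ≥50% → 1.  Bin edges are ambiguous in words ("between 12 and 18%");
  we fix lower-inclusive bins and document them.
* **Population-density score** (urban layer): zero density → 1;
  positive densities map to 2–5 through four equal-width, right-closed
  bins anchored at zero, (0, m/4] … (3m/4, m], where m is the maximum
  within the normalization unit.  The right-closed convention follows
  the worked bin example (0, 25], (25, 50], … for a unit topping out
  at 100.  An all-zero unit scores 1 everywhere.
* **Potential-yield score** (cropland layer): five equal-width,
  lower-inclusive bins over the unit's arable yield range, by analogy
  with the density rule; a constant-yield unit scores the midpoint 3.

Normalization units are countries for the urban layer and for the
*country* cropland scenario, regions for the *regional* scenario, so
scores are comparable only within a unit.

**Irrigated-vs-rainfed yield choice.**  Per country, cells with 2000
irrigation fraction ≥ θ = 0.10 form a reference set.  A cell takes its
irrigated potential yield when its (rainfed, irrigated) yield pair
lies within Mahalanobis distance `irrigation_strictness` (default 2.0)
of the reference centroid, with covariance from the reference set; the
reference cells themselves always take the irrigated yield, which
keeps the rule faithful to its motivation (significantly irrigated
cells and their look-alikes) even when the reference cloud is so tight
that its own members would fall outside a strict distance test.
Reference sets smaller than 5 cells use a per-feature-scaled Euclidean
distance; a zero-variance feature falls back to a tight 5% scale so
degenerate reference sets stay selective rather than swallowing the
whole country.  Larger strictness assigns weakly more cells.  The
exact matching procedure behind the original irrigation maps is not
fully specified anywhere we can reach, so this rule is a documented
reconstruction that reproduces the qualitative behaviour.

## Cellular allocation

Targets are split into `years` (default 15) annual cell quotas with
carried remainder.  Within a year, expansion repeatedly converts the
highest-scoring eligible cell 8-adjacent to the current extent,
re-evaluating the frontier after every conversion; when the frontier
empties, adjacency is waived for the remainder of that year's quota
(and entirely in units with no seed extent).  Ties are broken by a
seeded uniform jitter of magnitude 1e-6, far below the 12.5-point
score granularity, so runs are bit-reproducible under a fixed seed.
Contraction removes the lowest-scoring cropland first and relabels it
to the modal non-urban, non-cropland 2000 class of the cell's
ecoregion (grassland when an ecoregion has no natural land).  Realized
areas match targets to within one cell.  The cropland-to-urban loss CU
is measured ex post from the realized urban map, not assumed.

The original cellular engine's internal balance between suitability
and proximity is not published; strict frontier-first greedy with a
relax-to-anywhere fallback is our operationalization, and small-grid
behaviour is pinned to an exhaustive single-cell greedy oracle in the
tests.

## Agricultural accounting

Harvested area (multi-counted under double cropping) scales by the
multi-cropping-weighted growth of cropland cell area, w(σ1, σ2) =
σ1 + 2σ2: H′ = H·w(σ′)·C′ / [w(σ)·C], and likewise for the new-land
share, with H_old = H′ − H_new closing the identity to 1e-9 km².
Production applies technology growth γ (on the 2015 term only — the
2000 baseline is observed, so attributing the growth to the projection
period is the consistent reading), the land-quality inflators
ρ = mean suitability of a cropland subset over the 2000 cropland mean,
readiness δ (default 1), and crop-mix shares s^q.  The inflator enters
through the identity function f(ρ) = ρ: the published worked example
presents the suitability ratio itself as the yield inflator, and f is
exposed as a pluggable argument for anyone wanting a damped form.
New-land and old-land mixes default to equal (s_n = s_o) but are
independently settable.  With γ = ρ = δ = 1 and an unchanged mix,
production scales exactly with harvested area — asserted exactly in
the tests.  Calorie totals exclude the non-food oil-seed group; mass
totals include it.

## Water yield

W = P·(1 − AET/P) per cell and epoch, with AET/P =
(1 + ωR)/(1 + ωR + 1/R), R = k·ETo/P and ω = Z·AWC/P.  k is a
per-class evapotranspiration coefficient (defaults: forest ≈ 1.0,
cropland/grassland 0.65, urban 0.3, wetland 1.1), Z a per-basin
seasonality constant, AWC plant-available water content in mm; the
ω–AWC/P relation is linearized deliberately.  The fraction lies in
[0, 1), tends to 0 as R → 0 and to 1 as R → ∞, and is monotone in
both arguments (property-tested).  R > 1 flags potentially arid
cells; P = 0 cells carry NaN.  The early climate epoch pairs with the
2000 land cover and the late epoch with the 2015 map, standing in for
unavailable year-exact surfaces; "mm" is depth per unit area and
summaries are area-weighted means.  Rainfed cropland (cells not
assigned the irrigated yield) is summarized per country into the
area-change vs water-change quadrant table; the lower-right quadrant
(area up, water down) marks countries whose projected rainfed
expansion may be water-limited.

## Carbon and REDD

Carbon change per country is
[a_urb·z̄_u + a_crop·z̄_c − Z_j] + a_aband·(z̄_l − z̄_c) in Mg C with
areas in ha.  Z_j sums the per-cell 2000 storage over converting cells
(including cropland→urban cells at their cropland-level storage, as
the definition reads); the 2015 side uses country class means, and
abandoned cropland is credited at the mean over all less-intensively
managed classes rather than its assigned vegetation class — the more
conservative choice, and it makes the delta invariant to which natural
class an abandoned cell receives.  Countries missing a class fall back
to the global class mean.

REDD eligibility requires a developing country (HDI < 0.8, the "High"
cutoff; unclassified HDI counts as developing; configurable) with
projected annualized deforestation D = max(0, (F − F′)/(years·F))
above its historical baseline D_b.  The credit cap is
[(D − D_b)/D]·Σ_k A_jk·CO2_jk over forest types k cleared for
cropland; urban-driven clearing is never creditable.  Whether the
first term's share is annualized or cumulative is moot — the ratio is
scale-invariant.  Forest carbon given in Mg C converts at 44/12;
tables already in CO₂e declare so.  Participation is bang-bang
(strict inequality: price·cap > V·A) because only country-mean
opportunity costs V are available.

## The synthetic world

The generator emulates the statistical structure of the real input
stack, not its geography: Voronoi countries (round-robin into
regions), Voronoi ecoregions and basins; Gaussian-smoothed noise for
slope, yields, climate, soil and carbon surfaces; one contiguous urban
seed cluster per country at its population centre with a
distance-decay density field; a latitudinal cropland belt per country;
protected patches targeting ~10% of land (accepted range 5–15%),
never on cropland or urban.  Defaults: urban growth factors
U(1.15, 1.35) around the projected global ≈ +24%; country cropland
rates U(0.85, 1.30) and regional rates U(0.90, 1.25) so both signs of
change occur; baseline deforestation U(0, 0.01) yr⁻¹, overlapping the
scenario-projected rates so above-baseline acceleration is possible
but not guaranteed; agricultural NPV U(500, 20000) ha⁻¹; the late
precipitation epoch is the early one times a smooth field in
[0.7, 1.3] so water-yield change takes both signs.  Country carbon
means are recomputed from the rasters (consistent to 1e-9), harvested
area is drawn below the multi-cropping-weighted cropland area, and
infeasible urbanization targets trigger up to five shrink-and-retry
passes.  Crop-group attributes scale with HDI; the five crop-mix
matrices derive from a Dirichlet year-2000 base by shrinking non-staple
shares (steeply, moderately, barely, intermediately) and
redistributing to staples proportionally.

What the generator does **not** emulate: real-earth geography, the
GLC2000 legend beyond class roles, latitude-varying cell areas
(constant per world), spatially structured opportunity costs, or any
empirical covariance between, say, HDI and deforestation baselines.
Passing tests therefore demonstrate that the mechanics — allocation
order, conservation, closures, monotonicities, unit handling — are
right, not that real-world magnitudes would be reproduced.

A hand-set 12×12 two-country fixture accompanies the generator; every
downstream quantity on it (targets, conversions, carbon delta, credit
cap, participation flip between the $5 and $150 prices) is checkable
by hand and frozen in the tests.

## Numerical conventions and degenerate inputs

Integer rasters carry −1 nodata, continuous rasters NaN; areas are
km² (converted to ha inside carbon/REDD/production), yields Mg ha⁻¹,
water mm yr⁻¹, carbon Mg C ha⁻¹.  Cell counts for areal targets round
to the nearer of floor/ceil.  Countries without the relevant subset
(no new cropland, no rainfed cropland, no forest) get NaN/absent rows
and zero contributions rather than errors; zero-precipitation and
zero-area denominators are flagged.  All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; per-stage,
per-unit child seeds come from `SeedSequence` so scenario runs are
reproducible byte-for-byte (the run manifest records the seed and
input hashes).

## Problem sizes

The test suite exercises the 12×12 fixture, 40–60² generated worlds,
and one 200×200 four-country end-to-end pair of scenario runs (a few
seconds in total); the acceptance script uses the same 200×200
configuration.  These sizes were chosen because every mechanism the
package implements is already fully exercised at them; the engine
itself is O(cells · log cells) in allocation and scales to much larger
grids.

## Known limitations

Single-band TIFF I/O carries shape and cell-area metadata but no
georeference: inputs must be pre-aligned, and there is no
reprojection or resampling.  Mixed-cover cropland cells use a single
per-class k coefficient rather than a mosaic blend.  No road or
market-access drivers enter the suitability layers; no leakage or
permanence modelling enters the REDD accounting; the habitat proxy is
areal, with no species-level suitability or connectivity.
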