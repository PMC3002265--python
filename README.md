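# landcast

A global land-use-change scenario engine for landscape ecologists and
ecosystem-service modellers.  `landcast` spatially allocates projected
2000→2015 urban and cropland change on a gridded world with a
suitability-guided, annual-step cellular rule, then accounts for what
the new land-use map does to crop production (mass and calories),
annual water yield, biomass carbon storage, species habitat (an
undeveloped-land proxy), and the supply of avoided-deforestation (REDD)
credits.  Two cropland scenarios share one urbanization pattern: a
*country* scenario driven by country-level cropland growth rates and a
*regional* scenario driven by region-level rates, so differences between
them are entirely due to divergent cropland development patterns.

## The model

**Allocation.** Each country converts its urban-area increment ΔU_j =
U′_j − U_j cell by cell over 15 annual steps, preferring cells with
high urban suitability — the rescaled mean of a 1–5 slope score
(<12% → 5 … ≥50% → 1) and a 1–5 equal-interval projected-population-
density score — that are 8-adjacent to the existing urban extent.
Protected cells (IUCN I–VI) are never converted.  Cropland targets per
unit *u* (country or region) are

    C′_u = min(g_u · C_u, A_u)

with C the 2000 cropland grid-cell area, g the cropland growth rate
and A the arable area.  After urbanization removes CU of the 2000
cropland, net expansion C′ − (C − CU) is allocated on a cropland
suitability map (slope × potential cereal yield, the rainfed or
irrigated variant chosen by similarity to cells highly irrigated in
2000); net contraction abandons the lowest-suitability cropland to the
ecoregion's dominant natural vegetation.

**Accounting.** Harvested area grows at the multi-cropping-weighted
rate of cropland cell-area growth, w(σ1, σ2) = σ1 + 2σ2 over
single/double cropping-zone shares.  Production per country *j* and
crop group *i* follows

    cal′_ji = Y_ji · R_i · γ_ji · [ρ_n δ s_nji H_new + ρ_o s_oji H_old]

with Y the 2000 yield, R caloric density, γ technology growth, ρ the
land-quality inflators (mean cropland-suitability ratios, e.g.
55/49 = 1.12), δ infrastructure readiness, and s the crop-mix shares
(five alternative 2015 matrices).  Water yield is W = P·(1 − AET/P)
with the Budyko-curve fraction AET/P = (1 + ωR)/(1 + ωR + 1/R),
R = k·ETo/P, ω = Z·AWC/P.  Carbon change uses per-country class means:
ΔB_j = [a_urb·z̄_u + a_crop·z̄_c − Z_j] + a_aband·(z̄_l − z̄_c).  REDD
credits cap at the above-baseline share of cropland-driven forest CO₂e
and sell all-or-nothing when price·cap exceeds the agricultural NPV of
the threatened forest.

## Worked example

The bundled 12×12 two-country fixture is small enough to check by hand:

```python
import landcast as lc

world, table, crops = lc.make_fixture_small()
cfg = lc.ScenarioConfig(scenario_name="demo", seed=1)
run = lc.run_scenario(world, table, crops, cfg)
print(run.allocation.targets[["C", "C_prime", "C_new", "abandoned"]])
print(run.report.summary)
```

Country 1 has 20 km² of cropland, growth rate 1.25 and 40 km² of
arable land, so its 2015 target is `min(1.25·20, 40) = 25 km²`; the
5 km² of expansion clears the arable forest row next to the cropland
belt (the highest-suitability frontier).  Country 2 contracts
(g = 0.8), abandoning 4 km² of its lowest-scoring cropland to
grassland.  The run prints:

```
unit 1: C=20.0 C'=25.0 new=5.0 abandoned=0.0 dU=2.0
unit 2: C=20.0 C'=16.0 new=0.0 abandoned=4.0 dU=2.0

urban_area_change_km2      4.0
cropland_area_change_km2   1.0
carbon_delta_mg            -49994.1
undeveloped_gross_loss_km2 9.0
credits_by_price           {"5.0": 0.0, "150.0": 114583.3}
```

The carbon loss is dominated by 500 ha of 100 Mg C ha⁻¹ forest
converting to cropland (mean 5 Mg C ha⁻¹).  Country 1 clears forest
faster than its historical baseline (0.0133 vs 0.005 yr⁻¹), so it may
sell `(0.0133−0.005)/0.0133 × 500 ha × 100 Mg C ha⁻¹ × 44/12 ≈
114,583 Mg CO₂e` of avoided-deforestation credits — profitable at a
net price of $150 per Mg CO₂e but not at $5, the bang-bang
participation rule.

From a shell, the same pipeline is:

```bash
landcast synth --seed 3 --out world/       # write synthetic inputs
landcast run --config cfg.yaml --out run/  # allocate + account
landcast report --run run/                 # print report.json
```

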