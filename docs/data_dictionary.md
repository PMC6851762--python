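# Data dictionary

All tables are plain CSV. Times are (year, month) pairs; the monthly
index is t = 12·(year − year₀) + month with year₀ the first year of the
covariate record (t = 1 is January of year₀).

## Fire catalog (`fire_catalog.csv`)

| column | type | meaning |
| --- | --- | --- |
| event_id | int | unique event identifier |
| year, month | int | discovery year and month (1-12) |
| region | int | L3 region id |
| size_ha | float | total burned area, hectares; > threshold |
| exceedance_ha | float | size_ha − threshold (405 ha default); > 0 |

## Covariate panel / space-time panel (`covariates.csv`, `panel.csv`)

| column | type | meaning |
| --- | --- | --- |
| region | int | L3 region id |
| t | int | monthly index (see above) |
| year, month | int | calendar labels for t |
| humidity | float | mean daily minimum relative humidity, % |
| temperature | float | mean daily maximum air temperature, °C |
| precipitation | float | mean daily precipitation, mm/day |
| precip_12mo | float | cumulative precipitation over months t−12..t−1 (NaN for the first 12 months) |
| wind_speed | float | mean wind speed, m/s |
| housing_density | float | housing units per km² (strictly positive) |
| area_km2 | float | region area (panel only; count-model offset) |
| count | int | fires over the threshold in (region, t) (panel only) |
| split | str | "train" or "test"; a pure time cut (panel only) |

## Hierarchy (`hierarchy.csv`, `adjacency.csv`)

`hierarchy.csv`: columns l3, l2, l1 (region ids, one row per L3 region)
and area_km2. `adjacency.csv`: columns l3_a, l3_b — one row per unordered
adjacent L3 pair.

## True parameters (`true_parameters.json`)

Generative parameters of the synthetic study: count/size family names,
intercepts, full-length coefficient vectors (`beta_mu`, `beta_pi`,
`size_beta` in design-column order), NB dispersion, size-family
auxiliaries, AR coefficient and ICAR scale of the optional
spatiotemporal field.

## Design matrix serialization

Coordinate triples CSV (row, col, value) plus a JSON sidecar holding the
shape and per-column metadata (kind, covariate, basis_index, level,
region). Column order: global basis block, then L1, L2, L3 interaction
blocks (each sorted by covariate then region id), then intercept
adjustments (L1, L2, L3 by region id).
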