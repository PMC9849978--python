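# spatialaccess

Spatial-justice analysis of walking access to urban health facilities.

Urban health planning routinely has to answer three linked questions: are a
city's health centres *placed* with any spatial logic, is *poverty* spatially
clustered, and what share of the population — stratified by sex and age —
actually lives within walking reach of a centre? `spatialaccess` implements
the standard GIS workflow for these questions as a tested Python library:
point-pattern statistics, spatial autocorrelation of a block-level
deprivation classification, kernel density surfaces, and network-based
walking-time service areas overlaid with census-block populations. A
synthetic-city generator with controllable spatial structure makes the whole
pipeline reproducible end to end without any external GIS data.

It is aimed at health-geography and urban-equity researchers who want these
analyses scriptable and auditable rather than locked inside desktop GIS
tools.

## The statistics at the core

**Average nearest neighbour (ANN).** For n points in study area A, with
d̄_obs the mean distance from each point to its nearest other point,

    ANN = d̄_obs / d̄_exp,    d̄_exp = 0.5 / √(n/A),
    z = (d̄_obs − d̄_exp) / SE,    SE = 0.26136 / √(n²/A).

ANN ≈ 1 is consistent with complete spatial randomness, ANN < 1 clustering,
ANN > 1 dispersion. A defaults to the axis-aligned minimum enclosing
rectangle of the points.

**Global Moran's I.** For values x_i with deviations z_i = x_i − x̄ and
spatial weights w_ij (grand sum S₀),

    I = (n / S₀) · Σᵢ Σⱼ w_ij z_i z_j / Σᵢ z_i²,    E[I] = −1/(n−1),

with the normality-assumption closed-form variance for the z-score and an
optional permutation test. Weight schemes: inverse distance (default,
cutoff = max nearest-neighbour distance), distance band, k-nearest
neighbours, and rook (shared-boundary) adjacency for polygons.

**Kernel density.** Quartic (biweight) kernels of bandwidth h, with the
search-radius rule

    h = 0.9 · min(SD, √(1/ln 2) · D_m) · n^(−0.2),

where SD is the standard distance about the mean centre and D_m the median
distance to it. Surfaces integrate to total point weight (mass conserving).

**Walking-time access.** Facilities snap to the nearest street edge; a
shortest-path search with edge cost length/speed delimits the network
territory reachable within radius/speed seconds (default 750 m at 1 m/s,
i.e. 12.5 min), including partially covered frontier edges; covered edge
portions are buffered into service-area polygons, unioned, and intersected
with census blocks. Populations split areally (default) or by block
centroid, and are tabulated per sex × age stratum with exact
largest-remainder rounding, so access + no-access = total in every cell.

**Deprivation classes.** Block indicators are z-standardized, sign-aligned
so larger = more deprived, averaged with user weights, and cut into
terciles: lower (most deprived, the slum analogue), middle, upper.

## Worked example

`examples/04_three_wave_study.py` runs the bundled three-wave scenario: a
7 × 7 km synthetic city of 250,000 people with strongly clustered
deprivation (ρ = 0.8) receives nested facility waves of 29, 33 and 78
health centres:

```
walking cutoff: 12.5 min (750.0 m at 1.0 m/s)
poverty Moran's I: 0.446 (z = 17.4) -> clustered

year facilities    ANN  ANN z  no access %
1996         29   1.11   1.15        43.24
2006         33   1.16   1.77        37.79
2016         78   1.07   1.14         9.03
```

Reading: facility placement is indistinguishable from random (ANN ≈ 1,
|z| < 1.96) while poverty is strongly clustered (Moran z ≫ 1.96) — and as
nested waves add facilities, the share of residents living beyond a
12.5-minute walk of any centre falls monotonically. The other examples
(`01`–`03`) demonstrate the individual stages: point patterns, poverty
clustering, and one access table.

A thin CLI mirrors the stages: `spatialaccess generate | poverty |
pattern | access | run` (see `--help`); `run` executes a YAML study config
and writes `report.json` plus per-wave access tables.

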