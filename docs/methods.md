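# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions that matter.

## Scope and assumptions

All geometry is planar in metres (a projected CRS). The street network is
an undirected weighted graph: no one-way streets, turn restrictions or
crossing penalties — walking is assumed symmetric and unimpeded, which is
the standard simplification for pedestrian-access studies at city scale.
Census blocks are assumed to partition the study area; populations are
integer counts per sex × age stratum (0–14, 15–64, 65+).

## Point-pattern test (ANN)

`nearest_neighbor_stat` implements the classical Clark–Evans style ratio
with the conventional CSR null: d̄_exp = 0.5/√(n/A), SE = 0.26136/√(n²/A).
The study area A defaults to the *axis-aligned* minimum enclosing rectangle
(deterministic, matching the conventional desktop-GIS implementation), not
a rotating-calipers rectangle; pass `area=` to override. Coincident points
contribute a zero nearest-neighbour distance; ties need no tie-breaking
because only distances enter the statistic.

**Edge bias, quantified.** The CSR null ignores window edges. In a bounded
window, points near the border lack neighbours beyond it, inflating d̄_obs
by ≈ 0.051·P/n (Donnelly's boundary term; P the perimeter). For a square
this is a relative bias of 0.411/√n against a relative standard error of
0.523/√n — a z-shift of ≈ +0.79 SE *independent of n*. Consequently a true
CSR pattern falls inside |z| < 1.96 about 87–88% of the time, not 95%, and
the mean ANN ratio sits ≈ 1.3% above 1 at n = 1000. The tests assert the
mean ratio within 1 ± 0.02 and an in-band rate ≥ 80% (≈ 3.3σ below the
edge-bias-corrected expectation of 87.6% at 200 replicates); no edge
correction is applied because the uncorrected statistic is the one the
field's tooling reports.

## Spatial weights and Moran's I

The weights default is inverse Euclidean distance with cutoff equal to the
maximum nearest-neighbour distance (so no feature is isolated) and no row
standardization — the common desktop default. Alternatives: binary distance
band, k-nearest neighbours (used as-is, possibly asymmetric), and rook
adjacency for polygons (shared boundary of positive length). Isolated
features under a distance band are an error naming the features, never
silently zero rows.

Moran's I is the cross-product statistic over mean deviations. E[I] =
−1/(n−1) exactly. The variance under the normality assumption uses the
standard closed form with S₁ = ½·Σ(w_ij+w_ji)², S₂ = Σᵢ(rowᵢ+colᵢ)².
Because the normality assumption is often doubtful for class codings, a
permutation test (`inference="permutation"`) provides the assumption-free
alternative: the two-sided pseudo p-value is 2·(min(#I* ≥ I, #I* ≤ I)+1)/(n_perm+1),
capped at 1, with a caller-supplied seed for reproducibility.

Inference on *which* weights to use for a given dataset is left to the
user; results are reported with the scheme and parameters attached, since
Moran values are not comparable across weight conceptualizations.

## Kernel density

Quartic (biweight) kernel K(d) = 3/(πh²)·(1−d²/h²)² for d < h — compact
support, so density is exactly zero beyond h of every point, and each
point's kernel integrates to its weight. The default bandwidth follows the
search-radius rule h = 0.9·min(SD, √(1/ln 2)·D_m)·n^(−0.2) with SD the
(weighted) standard distance and D_m the weighted median distance to the
mean centre; n is total point weight. The √(1/ln 2) factor is the robust
median-based spread estimate (the median of a Rayleigh-distributed distance
equals SD·√(ln 2) under a Gaussian point cloud, so D_m/√(ln 2) estimates
SD robustly); this reading of the rule is an interpretation choice,
documented here because the rule circulates in typographically corrupted
forms. Mass conservation holds to < 1% at cell_size ≤ h/10 (tested by
quadrature).

## Walking-time service areas

Facilities snap to the foot of perpendicular on the nearest edge
(tolerance 200 m by default; farther facilities are an error, not
dropped; equidistant ties break on the lowest canonical edge id). The
service area runs Dijkstra from the snapped point, entering the network at
both ends of the snap edge, with travel time length/speed per edge. Edges
are covered up to the residual time budget from each reached endpoint —
plus direct coverage along the snap edge itself — yielding partial-edge
coverage at the frontier; covered portions are merged per edge.

Polygonization buffers the covered edge portions (default half-width
50 m). This is an artifact decision: desktop tools generalize service-area
polygons by their own undocumented rules, so polygons here are compared
only through the population counts they produce, never vertex-wise. The
demo scenario uses a 130 m buffer with 250 m blocks so that a block whose
entire perimeter is walkable counts as fully covered; with the 50 m
default, block cores beyond 50 m of any street can never be covered, which
caps areal access below 100% by construction — appropriate when "access"
should mean living *near a walkable street*, not merely in a touched
block. A Euclidean disc-union baseline (`euclidean_coverage`) is provided
for comparison but is not the default.

Population overlay: `areal` (default) splits each stratum count by the
block-area fraction inside coverage — the polygon-intersection semantics
of overlay tooling; `centroid` assigns blocks whole. Zero-area blocks fall
back to the centroid rule with a warning. Tabulation rounds the exact
fractional access/no-access pair to integers by largest remainder within
each stratum, so access + no-access equals the stratum total *exactly*;
percentages are 100·count/total rounded half-up to two decimals in exact
integer arithmetic (float rounding at the x.xx5 boundary would otherwise
misround).

## Deprivation index

Each indicator is z-standardized over blocks, sign-flipped per its
direction (so larger always = more deprived) and averaged with
user-supplied weights (equal by default). This makes the score invariant
to positive rescaling of any raw indicator, and flipping a direction flag
negates that indicator's contribution exactly. Classes are score terciles
— ordered (score descending, block_id ascending) and split into three
groups whose sizes differ by at most one; the most deprived tercile is the
*lower* class. Zero-variance indicators are dropped with a warning; a
fully tied score vector is flagged as degenerate (classes then reflect
only the tie-break). Equal-weight z-averaging with tercile cuts is the
minimal defensible aggregation when no weighting scheme is prescribed;
every element (weights, directions, coding) is configurable. For
autocorrelation testing the classes are coded ordinally (lower = 3,
middle = 2, upper = 1) or as a lower-class indicator.

## Synthetic city generator

The generator exists to make every downstream stage testable with known
ground truth; it aims at *statistical* realism of the features the
analysis consumes, not at street-map realism.

- **Roads**: an (nx+1) × (ny+1) grid graph with interior nodes jittered
  uniformly (clipped to 45% of block size so topology is preserved);
  connectivity is checked and regeneration attempted up to 5 times before
  failing. No OSM-style topology.
- **Blocks**: the unjittered grid cells — an exact tiling of the extent.
- **Population**: block weights exp(N(0, σ_log)) optionally multiplied by
  Gaussian hotspot kernels (amplitude 2 at centre); integer totals by
  largest remainder (conservation exact), then split into the six strata
  by largest remainder within each block. Default shares 0.15/0.32/0.03
  per sex approximate a young urban age pyramid.
- **Deprivation**: a simultaneous-autoregressive latent field
  z = (I − ρW)⁻¹ε with row-standardized rook W on the block grid;
  ρ ∈ [0, 1) is the single clustering dial (0.8 in the demo — strongly
  clustered, Moran z detection essentially certain at 20 × 20). Indicators
  are monotone logistic/affine transforms of the latent value plus small
  independent noise, on plausible scales (unemployment %, illiteracy %,
  literacy % reversed, dependency ratio, household size), plus population
  density derived from the population stage.
- **Facilities**: CSR (uniform), clustered (Thomas process: ≈ n/20 uniform
  parents, Gaussian offspring with σ = 2% of extent width, resampled into
  the extent — parameters fixed once so that n = 200 clustered placements
  are detected with z < −1.96 essentially always), or custom pass-through
  with extent validation.
- **Seeding**: one global seed split via `numpy.random.SeedSequence.spawn`
  into per-stage children (roads, population, deprivation, facilities; the
  pipeline's nested-wave placement uses a fifth child), so identical
  configs give byte-identical interchange files.

What it does *not* emulate: irregular block geometry, realistic street
hierarchies, correlated indicator measurement error, demographic change
between waves (wave populations are held fixed so access changes isolate
facility growth). Passing tests therefore demonstrate correctness of the
statistical machinery and the qualitative recoverability of clustered
poverty / random facilities / decoupled densities — not calibration to any
particular real city.

## Demo scenario

The bundled three-wave scenario (`demo_study_config`) is a 28 × 28 grid of
250 m blocks (7 × 7 km), 250,000 residents, ρ = 0.8, and nested CSR
facility waves of 29 → 33 → 78 centres with the 1 m/s / 750 m walking
model. The city size was chosen once so that 29 facilities cover roughly
half the population — the regime in which facility growth visibly moves
the access share; nesting guarantees coverage can only grow, so the
no-access share is non-increasing across waves (the structural property
the pipeline test asserts). Typical output (seed 7): no-access 43.2% →
37.8% → 9.0%.

## Numerical decisions

- Percentage rounding: half-up at two decimals via integer arithmetic
  (`pct_half_up`), immune to binary-float boundary error.
- Largest-remainder allocation breaks fractional ties by index (stable,
  deterministic).
- Service-area times use Dijkstra with float edge weights; the oracle
  tests compare against exhaustive simple-path enumeration at 1e-9 s.
- Moran's I and ANN cores are validated against naive O(n²) scans at
  1e-12 / 1e-9 on instances up to n = 500 / 2000.
- Weights matrices are scipy CSR sparse; the diagonal is forced to zero.
- Degenerate inputs fail loudly: < 2 points (ANN), zero-variance values
  (Moran, composite score), coincident points (bandwidth rule), zero-area
  enclosing rectangle (ANN without user area), lon/lat-looking coordinates
  (all readers).

## Known limitations

- No edge-corrected ANN or local statistics (LISA, Getis–Ord).
- Service-area polygons depend on the buffer half-width; only
  population-count comparisons are meaningful across implementations.
- The SAR deprivation field and Thomas process are one convenient choice
  each; the generator's API does not expose alternative field models.
- Car/transit travel, capacity-constrained catchments (2SFCA) and
  affordability dimensions of access are out of scope.
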