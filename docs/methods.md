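# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `grainvuln`, in the order a pipeline run encounters
them.

## Coordinate model and grids

All geometry is planar, in km, on regular square lattices. Row 0 of a grid
array is the southernmost row; the center of cell (r, c) is at
(x0 + (c + 0.5)·s, y0 + (r + 0.5)·s) for cell size s and lower-left origin
(x0, y0). Point-to-cell membership uses half-open intervals per axis so
boundary points are assigned deterministically. Distances between cell
centers are Euclidean; the package deliberately does not model great-circle
geometry, map projections or latitude-dependent cell areas — it targets
synthetic planar worlds and pre-projected equal-area grids.

**Aggregation.** A factor-f aggregation replaces each f×f block of fine
cells by the arithmetic mean of its non-missing members; an output cell is
missing only when its whole block is. Trailing partial blocks (dimensions
not divisible by f) average whatever cells exist, matching standard raster
aggregation semantics. Block means conserve the grid mean exactly when no
cells are missing, and shrink the variance of white noise by 1/f² — the
mechanism behind the grain dependence the package measures.

**Moran's I.** Spatial autocorrelation uses the plain cross-product
statistic with binary distance-band weights: w_ij = 1 for distinct included
cells whose centers are within the band distance, no row standardisation,
self-pairs excluded. Zero variance or an empty band raises a
degenerate-input error rather than returning NaN. The statistic is intended
to be computed on the finest-grain grid masked to a species' buffered
range.

**File formats.** Grids round-trip through single-band float64 GeoTIFF
(pixel-scale, tiepoint and nodata tags) and ESRI ASCII grid (nodata −9999).
The ASCII representation uses `repr(float)` so values survive a round trip
bit-for-bit at float64 precision.

## Occurrence handling

Occurrence tables are pandas DataFrames with columns
`species_id, x_km, y_km, year, month, travel_km`. Eligibility filtering
keeps records inside a year window (default 1981–2018), within a travel
distance (default 1 km), and inside the hemisphere-appropriate breeding
window — May–July for records with y ≥ 0, November–January otherwise. The
hemisphere is decided per record from the sign of y, which handles ranges
spanning the equator without species-level metadata.

**Spatial thinning** follows the randomized-greedy scheme popularised by
the spThin R package: while any retained pair is closer than the minimum
separation, delete one member of the currently largest conflict
neighbourhood, breaking ties uniformly with a seeded generator. The result
is a maximal conflict-free subset (no deleted point could be re-added),
deterministic given the seed, and idempotent. Exact maximum independent
sets are NP-hard and not attempted.

**Annotation** attaches to each record the mean of each variable over the
record's breeding months *in the record's own year* at the cell containing
the record, at whatever grain the supplied monthly layers have. Records on
missing cells or off the lattice are dropped with a logged count — values
are never interpolated. A missing (variable, year, month) layer is a hard
error naming the gap.

## Niche estimation

The niche model is a multivariate normal: center μ and covariance Σ of the
annotated environments. To damp spatial sampling bias, the estimator
averages over replicated thinning draws: each of `n_reps` (default 100)
replicates independently thins the full filtered pool to the minimum
separation (default 5 km) and computes the sample mean and sample
covariance (n−1 denominator); the reported μ and Σ are the element-wise
means of the replicate estimates. Each replicate is drawn from the full
pool rather than from a once-thinned set, so replicates differ by their
tie-breaking randomness. With thinning disabled and one replicate the
estimator reduces exactly to the plain sample moments, and it is affine
equivariant.

A species must retain more than `min_records` (default 20) records after
one thinning pass. Σ is declared singular — a degenerate-niche error — when
its smallest eigenvalue falls below 1e-12 of the mean eigenvalue. A ridge
ε·I can be added to Σ, but only on explicit request; nothing is regularised
silently.

## Vulnerability scoring

MD² is evaluated through a Cholesky solve (never an explicit inverse) and
clamped at zero against negative round-off. The per-variable components of
VS use the marginal variances; the interaction component is defined
*residually* as total − Σ univariate, which generalises to any n and, for
n = 2, coincides with the closed form
[ρ²(u−v)² + 2ρuv(ρ−1)]/(1−ρ²) (u, v standardized offsets, 1−ρ² the
determinant of the correlation matrix) evaluated at t1 minus at t0. The
residual definition makes the partition identity hold by construction;
the 2-D closed form is kept as an independent cross-check in the test
suite.

**Suitability kernel.** The primary weight is w = exp(−MD²), which is 1 at
the niche center — note this is *not* the standard Gaussian density kernel
(no ½ factor). The chi-square suitability-drop interpretation
(100·P(χ²_n ≤ VS)) uses MD² directly and is therefore internally consistent
with whichever kernel is chosen for weighting. A `kernel="half"` option
(exp(−MD²/2)) is available for sensitivity analysis. Weights are never
truncated or renormalised for extreme MD².

**Species-level EVS** is the w-weighted mean of pixel VS over the cells of
the aggregated grid whose centers fall inside the buffered range polygon
and that are non-missing at both periods; the same weighted mean is applied
to every partition component. The 95% interval is a seeded percentile
bootstrap over pixels (default 1000 resamples). The bootstrap treats pixels
as exchangeable; it understates uncertainty when pixel scores are spatially
autocorrelated, which they generally are — the interval is a Monte-Carlo
summary, not a design-based one.

## The grain ladder

`scaling_curve` runs the full pipeline independently at every grain of the
ladder (default 1, 2, 4, 8, 16, 32, 64, 128 km, each an integer multiple of
the finest): aggregate all monthly and period layers, re-annotate the
occurrences, re-estimate the niche (the fine-grain niche is never reused),
score all range pixels with grain-wise suitability weights, and form the
EVS. Range membership of a coarse cell is by cell-center inclusion. Every
grain gets its own spawned random stream from the run seed, so curves are
bit-identical across reruns and insensitive to execution order. Failed
grains are recorded with their stage and reason, never silently dropped;
grain dependence = EVS(finest successful) − EVS(coarsest successful), with
a warning when a ladder endpoint failed.

## Assemblage summaries

Range polygons are the union of the expert-range polygon (when given) and
all occurrence points, each buffered (default 50 km, a planar stand-in for
the 0.5° used with geographic data). A species "occupies" a coarse cell
when its buffered range overlaps the cell rectangle with positive area —
mere edge or corner contact does not count. Assemblage maps average
grain dependence over occupying species with weights 1/range-size; top-q
maps flag the ⌈q·S⌉ species with highest EVS (ties broken by EVS rank then
species id — a documented convention, not an inference about how others
break ties) and count occupying flagged species per cell. The driver table
exports one row per species × grain with EVS and all range/trait predictors
(empty, not zero, where unknown) for an external linear-mixed-model fit;
the model itself is out of scope.

Levin's dietary niche breadth is B = 1/(R·Σp²) over R diet categories: 1
for a uniform diet, 1/R for a single-category specialist.

## Synthetic worlds

The generator produces complete study systems with known truth, all pure
functions of (parameters, seed).

- **Random fields.** Base landscapes are zero-mean stationary Gaussian
  fields with exponential correlation exp(−d/ℓ), simulated by circulant
  embedding on a 2×-padded torus; the exponential kernel's occasional
  slightly negative embedding eigenvalues are clipped at zero, a
  perturbation that is negligible at this padding (verified against the
  target correlogram and sill in the test suite). ℓ = 0 is white noise.
  The exponential family was chosen because a single interpretable
  correlation length maps directly onto the Moran's-I heterogeneity
  narrative; Matérn smoothness control is out of scope.
- **Monthly structure.** A monthly layer is base + seasonal cycle (cosine,
  peak July) + a year anomaly. The anomaly is a white-noise field drawn
  once per (variable, year) and shared across that year's months. This
  year-level (rather than month-level) anomaly is deliberate: it makes the
  breeding-season mean of a record's year equal the exact condition the
  record was sampled under, so estimation can be validated against truth
  without a month-averaging bias term. The future condition t1 is the
  breeding-season mean t0 plus a deterministic shift, constant or gradient.
  Precipitation can optionally be clamped at zero; the option is off by
  default because clamping breaks the exact linearity of aggregation used
  in several invariants.
- **Virtual species.** Occurrences are rejection-sampled over uniform
  (cell, year, breeding-month) proposals, accepted with probability
  exp(−MD²/2) under the true niche — the standard Gaussian *density*
  kernel, a property of how a simulated species samples environments,
  independent of the exp(−MD²) weighting convention of the metric. Records
  carry cell-center coordinates and zero travel distance. The accepted
  environment distribution is the suitability-tilted landscape
  distribution, so recovered Σ is the harmonic combination of the true
  niche and the landscape covariance; fixtures keep landscape spread ≫
  niche breadth where exact recovery is asserted.
- **Fixture sizing.** Because occurrences resample a *finite* pool of
  distinct (cell, year) environments, recovery precision is limited by the
  suitability-weighted size of that pool, not just by n. The `white_noise`
  recovery fixture is therefore 96×96 cells × 10 years (≈92k distinct
  environments, ≈3k carrying appreciable weight for the default niche),
  comfortably supporting 3·standard-error recovery of μ at n = 2000.
  Element-wise Σ recovery is asserted on the correlation scale
  (|Σ̂ij − Σij| ≤ 0.1·√(Σii·Σjj)) so near-zero off-diagonals are not held
  to an unbounded relative standard.
- **Named fixtures.** `white_noise` (heterogeneous uncorrelated landscape,
  moderately narrow correlated niche), `autocorrelated` (ℓ = 10 km),
  `specialist` (niche SD 0.75 °C / 7.5 mm), `generalist` (20 °C / 200 mm,
  breadth ≫ landscape variability) and `uniform_shift` (constant exposure
  Δ = +1 °C / +10 mm). Under these parameters the specialist shows positive
  grain dependence and the generalist a smaller-magnitude negative one —
  an empirical contrast of the simulation, asserted at fixed seeds.

What passing tests on these worlds do *not* show: robustness to skewed or
truncated niche responses, observation effort and detectability biases,
taxonomic error, non-stationary landscapes, or dispersal — none of which
the generator emulates. The score itself measures niche displacement cost,
not extinction risk.

## Problem sizes in the default suite

Tests run the full ladder machinery at reduced scale chosen for the
properties they assert, not the sizes of a production study: scaling
properties use 16×16–32×32 landscapes over grains 1–8 km with 150–500
occurrences and 20 replicates (grain-ratio statements like 1/f² variance
shrinkage are scale-free), the chi-square law uses 1e5 draws, and the
recovery criterion uses the full 96×96 × 10-year white-noise world with
n = 2000. The complete suite finishes in about a minute on one CPU.
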