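# Methods

`hexdiv` analyses latitudinal and bathymetric gradients of marine
species richness from occurrence records, and ships a synthetic
occurrence generator with known ground truth so that every stage of the
analysis can be validated end to end. This note documents the models,
the numerical choices, and what the synthetic world does and does not
establish.

## Diversity measures

A **sample** is a unique combination of event date and location
(positions rounded to 4 decimal places, ~11 m; configurable). Three
richness measures are computed per ~50,000 km² hexagonal cell, per 5°
latitude band, and per 100-m depth interval:

- **alpha** — observed species count in the unit;
- **gamma** — observed species count of the enclosing region (band);
- **ES50** — expected species count in a random draw of m = 50 sampling
  units, the sampling-standardized measure.

Sample-based rarefaction uses Hurlbert's expectation over incidences:

    E[S_m] = S_obs − Σ_i C(N − n_i, m) / C(N, m)

with N samples and species i present in n_i of them. Binomial ratios are
evaluated in log-gamma space; underflow clamps terms to zero. A
record-based mode (per-species record counts; the classic
individual-based form, equivalent to vegan's `rarefy`) is also provided
— in that mode E[S_50] ≤ 50 is a theorem, while in samples mode E[S_50]
can legitimately exceed 50 because one sample may contain many species
(the sharp bound is min(S_obs, summed richness of the 50 richest
samples)). Units with fewer than m samples report ES50 as missing rather
than rarefying to a smaller m, keeping the statistic comparable across
units.

Standard errors come from a seeded bootstrap (default B = 200) that
resamples the N samples with replacement and recomputes E[S_m]; the SE
method is a package choice (the convention in the field does not pin one
down).

## Spatial units

The study box (0–90°N, 100–180°E) is tessellated with pointy-top
hexagons laid out in the plane of a spherical Lambert azimuthal
equal-area projection centred on the box. Because the projection
preserves area exactly, planar hexagons of 50,000 km² are spherical
cells of 50,000 km²; cells crossing the box boundary are clipped
(shapely) so cell areas sum to the spherical zone area of the box
(R²Δλ(sin φ₂ − sin φ₁), R = 6371 km; sphere throughout). Point-in-cell
assignment uses axial hex rounding in the projected plane, which
implements the nearest-planar-centroid rule deterministically; ties on
shared edges resolve to the nearer centroid.

Latitude bands are half-open [5k, 5k+5) with 90° closed into the top
band; depth intervals are half-open 100-m bins with 11,000 m closed into
the top bin; the shallow/deep split is depth ≤ 500 m vs > 500 m
(inclusive-shallow). Band ocean areas sum exact per-raster-cell zone
areas over ocean-mask cells.

## Driver models and AICc selection

Per-hexagon responses (alpha species counts, or ES50 rounded to the
nearest count) are fitted with negative-binomial (NB) log-link
regressions:

- each environmental covariate enters through a clamped cubic B-spline
  basis (5 functions) with a second-difference ridge penalty;
- spatial autocorrelation enters through a penalized tensor-product
  cubic B-spline surface over latitude × longitude (8 × 4 marginal
  bases, additive second-difference penalty). A real spherical-harmonic
  basis through degree 3 is retained as an option, but on a 90° × 80°
  window it is too stiff to absorb 8–12°-scale latitudinal richness
  structure, and in that regime *any* environmental spline acts as a
  flexible latitude transform and wins model selection spuriously — the
  tensor spline restores a fair comparison and is the default;
- sampling effort enters as centred log(records) and its square; the
  quadratic captures the saturating effort–richness relation (without
  it, hotspot residuals leak into whichever smooth covariate aligns by
  chance);
- one shared penalty weight λ is chosen by GCV (n·deviance/(n−edf)²) on
  a fixed grid of 7 log-spaced values, stiffest-first with warm-started
  refits;
- θ (NB dispersion) alternates between penalized IRLS for the
  coefficients and bounded 1-D likelihood maximisation (θ ∈ [10⁻², 10⁴];
  10⁴ is Poisson to numerical precision at these counts);
- effective degrees of freedom are the trace of the influence matrix
  tr[(XᵀWX + λP)⁻¹XᵀWX], +1 for θ; model ranking uses
  AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with ΔAICc < 2 flagged
  inconclusive. REML smoothing and double-penalty term shrinkage are
  deliberately out of scope; term selection happens only through the
  candidate set.

The candidate set per response/stratum: intercept-only; effort-only and
effort+spatial (species counts only — ES50 models exclude effort, since
ES50 already standardizes it); spatial-only; one model per environmental
predictor (each with spatial, and effort where allowed); and an
all-predictors model. Shallow models may use 8 predictors (temperature,
dissolved oxygen, productivity, chlorophyll, current velocity, oxygen
saturation, salinity, nitrate); the deep stratum drops the two surface
variables (productivity, oxygen saturation). This yields 13/11/11/9
candidates for species-counts/ES50 × shallow/deep.

Per-5°-band responses use plain Poisson GLMs with linear terms and a
log-records effort covariate (statsmodels; ~18 bands cannot support
smooths or a spatial term). The IRLS path is cross-checked in tests
against a brute-force likelihood grid search.

Non-converged fits are excluded from the selection table with a warning
rather than failing the run.

## The synthetic world

`generate_world` builds, deterministically per seed: environmental
fields, an ocean mask (all ocean except a mostly-land 60–70°N strip with
a 170–180°E window), an effort surface, a species pool, and the richness
surface the pool realises.

**Richness surface.** A bimodal latitude profile — Gaussian peak at 10°N
(σ = 12°), secondary peak at 80°N (σ = 8°, half amplitude), equatorial
Gaussian dip (σ = 4°), floored at a positive baseline — times an
exponential depth decay (e-folding 800 m below a 100-m onset). A
coupling coefficient c mixes this shape with a monotone exponential
transform of the coupling variable (temperature by default; elasticity
0.12 per °C, i.e. a ~e⁴ tropics-to-arctic contrast): at c = 1 richness
is a monotone function of temperature; at c = 0 it ignores the
environment's stochastic component entirely.

**Environment.** Each variable is a smooth basin-scale trend in latitude
and depth. Temperature is strictly decreasing in both. Regional
anomalies (3.5–6 longitude cycles across the box, ±5.5 °C-scale
amplitude, modulated by a slow latitude envelope that never overturns
the latitude trend) are carried by the *coupling variable only*; giving
every variable its own random anomaly field makes driver recovery
unidentifiable at the spline sizes used, because splines rescale
amplitude freely and some confounder's anomaly always aligns with the
spatially correlated residuals by chance.

**Species pool.** Box ranges with centres drawn from the richness
density (with the cos-latitude area factor for the lat/lon grid),
latitude widths ~8°, longitude widths ~12° (ranges elongated east–west),
depth ranges centred on draws from the depth profile; log-series
abundances (shape 0.98); a small cosmopolitan contingent (full box and
depth) guarantees every location has an admissible species.

**Sampling.** Effort is a uniform background plus Gaussian hotspots
whose centres are drawn richness-weighted (campaign effort concentrates
where biodiversity does). Sampling is *event-based*: each event draws a
location from the effort surface, one of its raster cell's
`dates_per_site` dates, and K ~ 1 + Poisson(records_per_sample − 1)
records, so per-sample intensity is independent of effort — the property
that makes ES50 comparable between lightly and heavily sampled cells
(with a site-based scheme, extra effort fattens samples and biases ES50
upward). Species are drawn among those whose range covers the record's
position and depth, with probability ∝ abundance^β: β = 0.7 − 0.45·ev,
where the evenness surface ev ramps linearly with the coupling variable
and is 0 at zero coupling. The base tempering (0.7 < 1) encodes that
occurrence archives under-record dominance; the energy–evenness ramp is
the coupling's second, pointwise channel — environmentally favourable
sites yield more distinct species per unit effort, exactly the signal
rarefaction measures.

**What a green test establishes.** The generator emulates the *
statistical* structure of a real extraction — gradients, effort bias,
abundance skew, date/location sample structure — not its taxonomic
composition, coastlines, bathymetry (depth is unconstrained by a depth
raster), temporal trends, or the record-level errors (transposed
coordinates, misidentifications) that real cleaning faces. Recovery
results show the pipeline detects what it is designed to detect in a
world obeying its assumptions; they are not evidence about any real
dataset.

## Validation experiments (tests/test_acceptance.py)

1. Closed-form rarefaction equals exhaustive subset enumeration for all
   tested incidence configurations with N ≤ 8 (plus the 3-sample worked
   example, E[S₂] = 5/3).
2. ES50 bound checks on a full synthetic run (samples mode: ≤ S_obs and
   the top-50 bound; records mode: ≤ 50 and ≤ S_obs).
3. Grid geometry: mean cell area within 10% of 50,000 km²; 10,000-point
   Monte-Carlo tiling check; band areas sum to the closed-form box area
   within 1%.
4. Effort robustness: one world sampled at 60,000 vs 6,000 records, 20
   replicates; paired per-cell ES50 differences average below 2 pooled
   bootstrap SEs while alpha shifts materially.
5. Gradient recovery over 20 seeded worlds: the band of maximum mean
   ES50 falls within one 5° band of the 10°N peak, and gamma declines
   beyond 2,000 m, in ≥ 90% of runs (measured: 20/20 and 20/20).
6. Model-selection recovery: with temperature coupling, the temperature
   or all-predictors model comes within ΔAICc 2 of the best in ≥ 80% of
   20 runs (measured: 17/20); with zero coupling the best model contains
   no environmental term in most runs (measured: 19/20).
7. Poisson IRLS matches a brute-force likelihood grid search; AICc
   closed-form spot checks.

Tests run the generator at 30-arcmin raster resolution (default
5 arcmin) and 6,000–80,000 records purely for runtime; no structural
parameter of the world differs from the package defaults.

## Known limitations

- Hexagons are not clipped to coastline (the ocean mask enters only
  band-area normalisation and effort placement), so cell areas near real
  coasts would overstate ocean area.
- The shared GCV λ across smooth blocks is cruder than per-term REML;
  with strongly heterogeneous smoothness it can over- or under-smooth
  individual terms.
- The spatial tensor spline absorbs environmental signal at wavelengths
  longer than ~30°; driver attribution rests on sub-basin-scale
  structure, mirroring the identifiability caveat the band-scale GLMs
  face even more severely.
- Sample identity assumes positions are reported consistently to ~11 m;
  datasets mixing coordinate precisions will fragment or merge samples.
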