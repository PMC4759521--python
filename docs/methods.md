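# Methods

## Ranges, bands, and interpolated richness

The sampling unit is the fixed-width elevational band; the default scheme is
nine 500-m bands from 500 to 5000 m (500 m is the conventional lower limit of
tropical montane gradients; the bandwidth is the standard compromise between
resolution and per-band sample size). A species' elevational range is
*interpolated*: the species is assumed present at every elevation between its
minimum and maximum records, so gamma richness per band is the count of
species whose closed interval `[min, max]` touches the band.

Band intervals are half-open `[low, high)` against closed species intervals.
Consequences, chosen to avoid double- or zero-counting at edges and covered
by tests: a species whose maximum sits exactly on a band edge still touches
the band above it (point overlap with that band's included lower edge); a
point range exactly on an interior edge belongs to the upper band only.
Records below the scheme base are clipped; presence below the gradient floor
is ignored. Derived columns (midpoint, range size) in input tables are always
recomputed, never trusted. Species known from a single locality get their
point range inflated by ±5 m (floored at 0 m) before null-model analysis,
since range shuffling requires nonzero sizes.

## Terrain

DEMs are regular geographic (lon/lat) grids read from ESRI ASCII or GeoTIFF
files; nodata cells are excluded from every statistic. Cell area uses the
spherical approximation `(cellsize · 111.32 km)² · cos(latitude)` — adequate
for the *relative* band areas the regressions consume, and exactly additive
under tiling (tested). A cell's band assignment uses the same half-open rule
as species interpolation.

The topographic ruggedness index is per cell
`TRI = sqrt(Σ₈ (e_center − e_neighbour)²)`. Cells with an incomplete
neighbourhood (grid edges or nodata neighbours) are excluded rather than
padded, avoiding biased edge ruggedness. Per band we report the *mean* TRI
over contributing interior cells (an aggregation the source material leaves
open; mean is scale-free in the number of cells). Region-level summaries are
the mean TRI over all interior land cells and the mid-latitude, defined as
the midpoint of the latitudinal extent of land cells (not an area-weighted
centroid); latitude is stored signed and converted to |degrees| at the
regression layer.

## Regression machinery

All fits are ordinary least squares. The SAR forms are linear (`S ~ A`),
semilog (`S ~ log₁₀ A`) and curvilinear (`log₁₀ S ~ log₁₀ A`); the
curvilinear slope is the power-law exponent z (base-invariant). Rows that are
non-positive under a log transform are dropped pairwise and logged (or raise,
per configuration).

AICc is computed from the Gaussian log-likelihood with the error variance
counted as an estimated parameter (`k = n_regressors + 1`), i.e.
`AICc = AIC + 2k(k+1)/(n−k−1)` — the convention of the ecological
model-selection literature. Akaike weights are
`exp(−Δᵢ/2)/Σ exp(−Δⱼ/2)`; two numerical guards exist for degenerate cases
(a perfect fit with infinite likelihood takes all the weight; underflowed
weights collapse onto the best model). Model sets whose members model
differently transformed responses (linear vs. log-log) are compared by their
AICc values directly, as is customary in this literature even though the
likelihoods are not strictly commensurable across response scales; an
optional Jacobian correction (`jacobian=True`) maps log-response likelihoods
back to the raw scale and is off by default.

Both r² and adjusted r² are reported. Adjusted r² — which can be negative
for uninformative fits — is the headline statistic for SAR/TRI/MDE model
tables; a zero-variance response is reported as r² = 0 with slope 0 rather
than the indeterminate ratio.

**Global z** is the mean curvilinear slope across gradients whose power-law
SAR is significant (p < α, default 0.05), with a 95 % t-interval on the
slope sample; it requires at least two contributing gradients. **Area
correction** deflates a richness curve by `S/A^z` and rescales so the
corrected maximum equals the empirical maximum — shape-preserving, and
invariant to multiplying all areas by a constant (both tested). The exact
normalization of corrected curves is an open choice; max-matching keeps the
corrected and empirical curves directly comparable in one panel.

**Topographic-heterogeneity models** reuse the three forms with band mean
TRI as the predictor, or TRI/√area when deflating ruggedness for band size.
Richness is always the response; bands with missing TRI are dropped
pairwise.

**Latitudinal models.** One row per mountain range (regional richness,
mid-latitude, region mean TRI, mid-elevation of the regional species pool,
defined as the midpoint between the lowest and highest records). Four models
are fitted — richness ~ |lat|, ~ |lat| + elevation, ~ |lat| + TRI, and
intercept-only — and compared by AICc. Coefficients are *naturally*
model-averaged: a parameter is averaged only over the models containing it,
with those models' Akaike weights renormalized (computed stably from
delta-AICc differences within the subset). Latitude enters as absolute
degrees from the equator by default (richness gradients in this system peak
near the equator and decline both ways); a signed-latitude flag exists.

## Mid-domain null model

Each Monte-Carlo simulation takes the complete empirical multiset of range
sizes exactly once ("without replacement" — pure midpoint randomization; a
with-replacement variant bootstraps the sizes each simulation) and draws each
range's midpoint uniformly from its feasible interval
`[low + size/2, high − size/2]`, continuous, with no discretization to band
edges — matching the constrained-null literature and avoiding grid
artifacts. Per-band richness is tallied with the same interval-overlap rule
as empirical interpolation. Across simulations (default 50,000) the result is
the per-band mean and the 2.5th/97.5th percentile envelope (per band, not a
simultaneous band). Oversized ranges are clipped to the domain span with a
warning; zero-size ranges are rejected with a pointer to the ±5 m inflation.
Results are bit-reproducible for a given seed.

The domain defaults to `[scheme base, top edge of the highest band with land
or species]` and is overridable per region in the configuration, which also
records it in the run log — domain tops are a genuine ambiguity and they
change the fit statistics. The fit of the empirical (or area-corrected)
curve on the null mean uses linear and quadratic OLS — df (1,7) and (2,6) at
nine bands — compared by AICc.

The Monte-Carlo band means are validated against an independent
deterministic oracle (fine-grid integration of the per-species band-coverage
probability over the feasible midpoint interval) to within three Monte-Carlo
standard errors; the analytical route is used only for testing, never as the
primary path.

## Synthetic data

The generator emulates the two study inputs at realistic scale. Species
sets: range sizes default to a lognormal law (right-skewed, like empirical
elevational range-size distributions; default median ≈ 700 m, σ = 0.8 on the
log scale) clipped to the domain span; midpoints are either `mde_uniform`
(uniform on the feasible interval — the null model is true by construction,
the generator's main diagnostic role) or `niche_normal` (clustered around an
elevational optimum, giving hump-shaped profiles whose cause is niches, not
geometry). DEMs are cross-sectional ridges: a convex flank profile (exponent
2) gives band areas that decrease monotonically with elevation, as in the
northern tropical Andes; an optional near-flat bench at a chosen elevation
produces an interior band-area maximum, as altiplano hypsometry does; the
ridge axis is sheared by one cell north-to-south so band hypsometry is
smooth rather than quantized to whole columns; i.i.d. Gaussian noise of
chosen amplitude sets the ruggedness.

`make_study_standin` is a synthetic stand-in for a compiled Andean rain-frog
database: 378 species, records pinned to span 500–4538 m, niche-clustered
midpoints (optimum 2400 m, sd 900 m). It reproduces the scale and hump shape
of such a compilation, *not* its actual values: a synthetic curve is smoother
than a real one (no sampling noise, no localized deviations from the null),
so statistics such as the empirical-vs-null r² tend to run higher on the
stand-in than on real data. Passing tests on synthetic data demonstrate the
correctness of the machinery and parameter recovery, not the empirical
conclusions one would draw from real databases.

The toy mountain system (`make_mountain_system`, `elevdiv fixtures`) places
six cordilleras at distinct latitudes from 8°N to 15°S with regional species
totals declining at −4.55 species per degree of absolute latitude (plus
noise), southern regions carrying plateau hypsometries. Six regions (rather
than a minimal three) because the latitudinal stage requires at least five
points to fit four models meaningfully.

## Problem sizes and numerical choices

Default test and reproduction scales — chosen so the whole pipeline runs in
seconds while keeping Monte-Carlo error well below the tolerances tested:
5,000 null-model simulations for the study-scale fit (the envelope and means
stabilize well before that; 50,000 remains the library default), 400–4,000
simulations inside property tests, DEM tiles of 30–200 cells per side,
200–400 species per gradient, and 100–500 replicates for coverage and
detection checks. Seeds are explicit everywhere; per-gradient seeds in the
pipeline are spawned from the run seed via `numpy` seed sequences, so
adding a region does not perturb the others' draws.

## Limitations

* Areas use the spherical cosine approximation; absolute km² values carry
  that approximation even though relative band areas (all the regressions
  use) are barely affected.
* No spatial autocorrelation correction, GLS, or hierarchical multi-gradient
  model; fits are independent OLS per gradient.
* Region membership comes from the input table; the package does not
  georeference occurrence records or delineate mountain ranges from
  polygons (regions arrive as pre-cut DEM tiles).
* The null model randomizes midpoints in one dimension; two-dimensional
  range-cohesion nulls are out of scope.
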