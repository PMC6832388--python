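# Methods

## The model

The analysis treats terrestrial vertebrates as embedded in three coupled
systems: the climatological rainfall–runoff chain, the food chain proxied
by vegetation greenness, and the human environment proxied by nighttime
lights.

**Energy–water coupling.**  Net radiation N partitions into latent
(evapotranspiration E) and sensible (H) heat flux, N = E + H, all in
water equivalents of m/yr.  Energy fluxes supplied as half-day integrals
(J m⁻² per 12 h) are converted with the latent heat of condensation
L = 0.25 × 10⁷ J kg⁻¹ and water density 10³ kg m⁻³:
one input unit ↦ 2 × 365 / (L ρ) = 2.920 × 10⁻⁷ m/yr.  The dryness ratio
D = N/P relates demand to supply (precipitation P) and classifies
geobotanic regimes: tundra (D < 1/3), forest (1/3 ≤ D < 1),
steppe/savanna (1 ≤ D < 2), semi-desert (2 ≤ D < 3), desert (D ≥ 3).
Regime boundaries are assigned to the drier class (half-open intervals);
this is a documented convention, configurable in principle by comparing
against the boundary constants directly.  Schreiber's equation of state
E/P = 1 − exp(−D) closes the system and yields two isoline families in
the (E, H) plane:

* constant precipitation:  H = −P ln(1 − E/P) − E,  0 ≤ E < P;
* constant dryness:        E = H (1 − e⁻ᴰ) / (D − 1 + e⁻ᴰ),  H ≥ 0, D > 0.

Both parameterize the same surface, so a (D, H) point mapped through the
dryness isoline and back through the precipitation isoline returns its
dryness ratio; the implementation round-trips to ~1e-13, and the test
suite requires 1e-8 over 10⁴ random points.  The dryness-isoline
denominator D − 1 + e⁻ᴰ behaves as D²/2 near zero; inputs driving it
below 1e-12 are rejected with an explanatory error rather than returning
an overflowed ray.

**State-space embedding** is a weighted 2-D histogram over (E, H) bins.
Pixels with E ≤ 0 or H < 0 are excluded and counted in a diagnostic
(`n_excluded`): the equation of state is undefined there, and
reanalysis-style fields do produce such pixels.  Bin widths and the
smoothing method are free choices here; the default is 50 equal bins per
axis spanning the valid data and Gaussian smoothing with a 1-bin
bandwidth under reflective boundaries, which conserves mass to machine
precision.

**Cities** are 8-connected components (configurable to 4) of pixels with
DN ≥ 12; the threshold is inclusive and exposed as a parameter.
Components do not join across the ±180° seam unless a wrap flag is set.
City size is the sum of member spherical-quadrilateral pixel areas
(radius 6371.0 km throughout).  Sizes are binned into a base-2 km²
exponential spectrum — bin 0 is (0, 2), bin k is [2·2ᵏ⁻¹, 2·2ᵏ) — and
for sizes drawn from a discrete power law with exponent s the expected
log₂-count slope across bins is 1 − s, which is how the spectrum fit
reports a recovered exponent.  Cities are extracted at the native fine
resolution; coarse-grid stratification uses fractional cover computed by
area-weighted aggregation of the fine lighted mask (a cell counts as
"city" for binary statistics when cover exceeds 0.5).

**NDVI-conditioned statistics** use half-open bins [T, T + 0.1) with
T ∈ {0.0, …, 0.9}; NDVI exactly 1.0 joins the last bin, and negative
NDVI is excluded as non-vegetated (it appears in percentage curves as an
explicit out-of-range remainder, so fractions always close to 1).  The
threatened species indicator is aggregated as the ratio of the bin sums
(Σ threatened / Σ abundance), not the mean of per-pixel ratios — only
the ratio of sums cancels the area/population effect that makes raw
abundance comparisons between city and land misleading.  The coefficient
of NDVI variability is the per-pixel ratio of the annual standard
deviation (population normalization, ddof = 0, configurable) to the
climatological mean, masked where the mean is non-positive or fewer than
3 years are valid; per-bin summaries are area-weighted means.  "Land"
always means city plus non-city, so bin sums over the two strata equal
the land sums exactly — an invariant the tests assert bit-for-bit.

**Trend comparison.**  Per stratum, an annual area-weighted mean NDVI
series is formed over pixels whose *climatological* NDVI lies in a fixed
interval (membership does not change year to year), and fit by ordinary
least squares against year.  The classification rule is a deliberate
heuristic made explicit and configurable: green requires
slope_city/slope_land ≥ 2 (default `green_ratio_min`) with a positive
city slope; brown is |ratio − 1| ≤ 0.25 (default `brown_band`) or a
non-increasing city slope; everything else is indeterminate.  Land
slopes below 1e-6 NDVI/yr leave the ratio undefined and the decision
falls back on slope signs.

## The synthetic worlds

The generator's defaults define the study conditions: a 200 × 200 grid
of ~1 km cells (0.009°) centered on the equator, 32 annual layers
(1982–2013 analogue), 120 cities with pixel areas from a discrete power
law with exponent 2 truncated at 512 px, NDVI climatology uniform on
[0, 1) (so every 0.1 bin holds ~10% of the area), residual NDVI noise
SD 0.01, abundance ~ Poisson(20 + 180·NDVI), and threat probabilities
π(bin): flat 0.1; U-shape 0.02 + 0.01·(b − b₀)² with the minimum at the
0.3 bin; step jump 0.05 → 0.25 at the 0.4 bin.  Two named regimes bundle
the planted trend structure: `china` (city slope 0.003, non-city 0.001
NDVI/yr, U-shape profile) and `america` (equal slopes 0.002, step-jump
profile).

City blobs grow by randomized dilation from seed pixels to the target
pixel count, which keeps them 4-connected by construction; blobs placed
close enough to touch merge, and the truth record logs the resulting
component count.  Flux triples are generated directly on the Schreiber
surface (E = P(1 − e⁻ᴰ), H = PD − E), making the embedding and isoline
consistency suites exact tests rather than approximations.  Threatened
counts are a binomial thinning of abundance, which guarantees
indicator ∈ [0, 1]; real species layers do not guarantee this (abundance
and threatened counts are independent rasters), so passing the planted
recovery tests shows the statistics machinery is correct, not that real
data satisfy the bound.

Other features of real data the generator deliberately omits: spatial
autocorrelation in climate and NDVI noise, continental geography and
coastlines, sensor artifacts (over-glow, intercalibration drift), and
range-map rasterization effects.  Recovery results should be read as
verifying the estimators under clean planted structure.

**A note on the planted trend ratio.**  `slope_land` is applied to
non-city pixels, but the comparison is city versus *land* (city +
non-city, matching the land definition above).  The land-average slope
is therefore a cover-weighted mixture; at the default ~1% city cover the
measured ratio under planted 3:1 slopes is ≈ 2.93, not 3.00.  This is a
property of the land definition, not estimator bias, and lies well
inside the ±0.3 recovery band the tests use.

## Numerical choices

* Cell registration: values are cell means at cell centers; all
  resampling is center-to-center bilinear, exact on affine fields.
  Under nodata, stencil weights are renormalized over valid neighbors by
  default (masking only when all four contributors are invalid), which
  avoids eroding coastlines when coarsening; a strict `mask` policy is
  available.
* Grids are stored south-to-north; GeoTIFF rows are flipped on I/O.
  GeoTIFF georeferencing is written/read via the ModelPixelScale,
  ModelTiepoint and GDAL nodata tags; time stacks use NetCDF3 classic
  files with CF-style lat/lon/time coordinates plus explicit cell-edge
  variables so geometry round-trips exactly.
* NDVI bin edges are rounded to 10 decimals so bin thresholds like 0.3
  are exact in exported tables.
* Empty NDVI bins and empty size-spectrum bins are retained with masked
  (NaN) statistics rather than dropped, keeping table shapes stable.
* All generators take explicit integer seeds and are bit-reproducible
  for integer layers, 1e-12-reproducible for floats; the pipeline
  manifest records a config hash and per-artifact checksums, and
  re-running a config reproduces byte-identical artifacts.

## Scale of the shipped analyses

The test suite and the acceptance script run the recovery batteries at
100 seeds on the default 200 × 200 / 32-year world, the Budyko
round-trip at 10⁴ points, and city-labeling fidelity on 100 random
30 × 30 fixtures; the full acceptance run completes in well under a
minute on one CPU.  The Zipf-exponent recovery uses 500 cities on a
400 × 400 grid to populate enough spectrum bins for a stable slope fit.

## Known limitations

* Only geographic lat/lon grids; no projection engine.
* The green/brown decision rule is a two-parameter heuristic encoding a
  "several-fold city greening" versus "land-like trends" contrast; it is
  exposed in the config precisely because other thresholds are
  defensible.
* No significance testing of trends and no breakpoint detection.
* NetCDF support is NetCDF3 classic (no groups, no compression).
* The regional summary table assumes species layers are already gridded
  counts; rasterizing polygon range maps is out of scope.
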