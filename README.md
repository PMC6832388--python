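# greencities

Raster analysis of how urbanization, vegetation greenness and climate
jointly shape the geography of threatened vertebrates.

The package is aimed at spatial ecologists and remote-sensing analysts
working with co-registered gridded layers: nighttime-light brightness
(integer DN 0–63, DMSP/OLS-style), annual NDVI series (GIMMS-style),
climatological surface fluxes and precipitation (reanalysis-style), and
vertebrate species-richness / threatened-species count rasters.  It
implements four linked analyses:

1. **City extraction.**  Cities are spatially contiguous lighted pixels
   with DN ≥ 12; each connected component *j* is a city of size
   size(*j*) = Σᵢ aᵢ(*j*), the sum of its member pixel areas.  City counts
   are summarized in a Zipf-style spectrum over exponentially widening
   size bins (base 2 km²).
2. **Eco-hydrological embedding.**  The land-surface energy balance
   N = E + H (net radiation into evapotranspiration and sensible heat, in
   water equivalents of m/yr) and the water balance are coupled through
   the dryness ratio D = N/P and Schreiber's equation of state
   E/P = 1 − exp(−D).  Isolines of constant P and D are drawn in the
   (E, H) plane (Stephenson's diagram), dryness regimes (tundra → desert)
   are classified on D, and any layer can be embedded as a weighted 2-D
   frequency distribution.
3. **NDVI-conditioned statistics.**  Species abundance, the threatened
   species indicator (threatened count / abundance, aggregated as a ratio
   of sums per bin) and the coefficient of NDVI variability (σ/μ of annual
   NDVI) are computed in half-open NDVI bins [T, T + 0.1) for city,
   non-city and land (= city + non-city) strata, together with NDVI- and
   city-percentage area curves and regional summary tables.
4. **Trend comparison.**  Annual-mean NDVI series per stratum are fit by
   OLS; the city-over-land slope ratio classifies a *green* city effect
   (cities out-greening land, ratio ≥ 2 with a positive city slope) versus
   a *brown* effect (land-like trends or declining city greenness).

A fully ground-truthed synthetic-data module generates all four layer
families (power-law city blobs, planted per-stratum NDVI trends,
Schreiber-exact flux triples, Poisson/binomial species counts with
planted U-shape or step-jump threat profiles), so every stage is testable
without downloading satellite archives.

## Worked example

```python
import greencities as gc

world = gc.make_world(seed=7)            # 200x200 ~1 km cells, 32 years
table = gc.city_size(gc.extract_cities(world["lights"]), world["areas"])
spec = gc.size_spectrum(table)
print("n_cities:", table.n_cities)
print("spectrum counts:", spec.counts.tolist())

comp = gc.compare_trends(world["ndvi_series"], world["city_mask"],
                         world["land_mask"], (0.0, 1.0),
                         world["ndvi_clim"], areas=world["areas"])
print(f"slope_city={comp.slope_city:.5f}  slope_land={comp.slope_land:.5f}  "
      f"ratio={comp.ratio:.2f}  effect={comp.effect}")
```

prints

```
n_cities: 120
spectrum counts: [80, 24, 10, 2, 2, 2, 0]
slope_city=0.00297  slope_land=0.00101  ratio=2.93  effect=green
```

The 120 planted cities bin into a spectrum that roughly halves per
doubling bin, the signature of a size power law with exponent ≈ 2.  The
planted city trend (0.003 NDVI/yr) and non-city trend (0.001 NDVI/yr) are
recovered; the measured ratio 2.93 sits slightly below 3 because "land"
includes the city pixels themselves, and the classifier labels the run a
green city effect.  Binned threatened-indicator statistics for the same
world recover the planted U-shape with its minimum in the 0.3–0.4 NDVI
bin:

```python
stats = gc.bin_stats(world["ndvi_clim"], world["abundance"],
                     world["threatened"], world["land_mask"],
                     areas=world["areas"])
print(stats[["ndvi_lo", "indicator"]].round(4).to_string(index=False))
```

The same analyses run from the shell via the `greencities` console
script (`simulate`, `extract-cities`, `embed`, `bin-stats`, `trends`,
`table1`, `validate`, `run`), driven by a small YAML config.

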