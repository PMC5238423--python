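# migraphen

Migration phenology from GPS tracking data — a reusable, tested pipeline for
the full analysis chain used in telemetry studies of short-distance migratory
birds (the motivating system is the American white pelican, wintering on the
Gulf of Mexico coast and breeding in the Northern Great Plains):

1. **Seasonal ranges** — fixed-kernel utilization distributions of pooled
   relocations with the bivariate normal reference bandwidth
   h_ref = σ̂·n^(−1/6) scaled by 0.8; the 95% isopleth polygon is the range.
   Breeding ranges from colony/survey points come from a convex hull.
2. **Migration timing** — net squared displacement (NSD), the squared
   great-circle distance from the first fix inside the non-breeding range:

       NSD(t) = δ/(1+exp((θ_s−t)/φ_s)) − δ/(1+exp((θ_a−t)/φ_a))

   fitted by multi-start least squares and compared by AICc against a
   constant-NSD (resident) model. The four annual-cycle dates (spring
   departure/arrival, autumn departure/arrival) are read off the track with
   explicit persistence-based boundary-crossing rules against the range
   polygons.
3. **Vegetation phenology** — double-logistic seasonal fits to regional NDVI
   composites; green-up is the spring day the curve reaches 50% of the annual
   amplitude above the base level.
4. **Winter climate** — mean daily temperature and total precipitation (cm)
   for the Nov 1 – Jan 1 window from daily station records.
5. **Repeatability** — intraclass correlation r = σ²_b/(σ²_b+σ²_w) of each
   migration date across years within individuals (one-way ANOVA estimators
   with the unbalanced-design correction), with a label-permutation test
   (default 5,000 permutations).
6. **Trend and climate models** — cross-sectional year-trend linear models
   with an exact-ML AR(1)-error alternative; longitudinal random-intercept
   mixed models (`date ~ year + age + temp + prec + temp*prec + (1|ID)` and
   subsets) ranked by AICc; and the detrended (spurious-correlation) check
   `ddate ~ dgreenup + age + dgreenup*age + (1|ID)` on OLS year-residuals.

Because raw multi-year tracking data of this kind are rarely public, the
package ships a first-class synthetic-data generator (`migraphen.synthetic`)
that produces hourly GPS fixes with ~18 m positional noise and fix dropout,
resident and migrant birds with individual-specific spring departure dates
(target repeatability 0.76, advancing −6.44 d/yr), 16-day NDVI composites
with an advancing green-up (−1.61 d/yr), and station weather — together with
the ground-truth tables that make every downstream stage testable.

## Worked example

```python
from migraphen.pipeline import PipelineConfig, run_pipeline

results = run_pipeline(PipelineConfig(), "out")   # default synthetic study

dep   = results["cross_sectional"]["population_departure"]
icc   = results["repeatability"][("spring_departure", "detrended")]
green = results["phenology_trends"]["non_breeding"]
```

With the default configuration (12 residents + 24 migrants, 2002–2011,
hourly fixes, seed 0) this prints:

```
median spring departure (doy):   84.4
departure trend:  -6.29 d/yr (se 0.56)
departure repeatability r=0.782 (p=0.0002, 24 birds, 72 bird-years)
green-up trend:   -1.76 d/yr (se 0.14)
successive-year departure differences: mean 7.4 d (range 0-20, n=48)
```

The estimated departure trend (−6.29 d/yr) and detrended repeatability
(0.782) recover the generating values (−6.44 d/yr, 0.76) within sampling
error; the median departure is low because ten years of a −6.44 d/yr advance
pull the later years far forward of the initial May 1 departure. `out/`
contains `migration_dates.csv`, `repeatability.csv`, `phenology.csv`,
`climate.csv`, `model_selection.csv`, `coefficients.csv`, the range polygons
as GeoJSON, and a run log. The same run is available from a shell:

```sh
migraphen run --out out --seed 0
migraphen simulate --out sim --seed 0          # just the synthetic inputs
migraphen run --config cfg.yaml --set simulate.n_migrants=12 --set n_perm=1000
```

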