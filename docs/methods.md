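# Methods

This note records the models implemented in `migraphen`, the defaults and the
reasoning behind them, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Geometry

All distances are great-circle distances on a sphere of radius 6371.0088 km;
net squared displacement therefore measures true kilometres over the
~2,000 km migration corridor, where planar approximations are materially
wrong. Kernel density estimation works in a Lambert azimuthal equal-area
projection centred on the centroid of the points being smoothed: an
equal-area plane is what keeps the "95% of the utilization distribution"
interpretation of an isopleth honest. The projection is exact on the sphere;
round-trip error is below a metre anywhere within 2,000 km of the centre
(property-tested).

## Home ranges

The utilization distribution is a fixed-kernel estimate: points are binned
on a grid (250 cells on the longer axis, padded three bandwidths beyond the
data extent) and convolved with an isotropic Gaussian of bandwidth
0.8·h_ref, where h_ref = σ̂·n^(−1/6) is the bivariate normal reference
("ad hoc") rule with a single pooled σ̂ = sqrt((var_x+var_y)/2). The
exponent and the pooling are stated because variants of the rule exist in
the home-range literature. The isopleth at level p is the contour of the
smallest set of highest-density cells whose cumulative probability reaches
p, ties included; the binned-convolution estimator makes 10,000-point
utilization distributions essentially free, and the empirical coverage of
the 0.5/0.8/0.95 isopleths on Gaussian test samples is within ±0.03 of
nominal (tested). The density mode is reported as the density-weighted
centroid of cells above 80% of the peak — the raw argmax cell wanders on a
flat-topped density.

Containment of a fix in a range polygon is boundary-inclusive, so a bird
sitting exactly on the edge never flickers between "present" and
"departed". Seasonal "super" ranges pool relocations across birds before
smoothing. The breeding range is a plain convex hull of colony/survey
points.

## NSD migration model

The NSD reference point is the first fix inside the non-breeding range of
the annual cycle. Hourly NSD series are aggregated to daily medians before
fitting: the migration signal lives at the daily scale and the median damps
the heavy-tailed within-day wander. The double logistic

    NSD(t) = δ/(1+exp((θ_s−t)/φ_s)) − δ/(1+exp((θ_a−t)/φ_a))

is fitted by bounded least squares from a deterministic multi-start grid
(spring/autumn half-plateau crossings of the data, ±10-day shifts, a fixed
fallback; φ started at 2 and 8 days), with θ_a parameterised as θ_s + gap,
gap ≥ 1 day, so the ordering constraint is structural. A constant-NSD model
is fitted alongside and both AICc values reported. A bird-year is classified
migrant only when (a) the double logistic beats the constant model by AICc
and (b) the fitted plateau δ exceeds (100 km)² — on mean-reverting resident
tracks a five-parameter curve can chase noise past a two-parameter constant,
and a "migration" of under 100 km is not one. On noiseless curves all five
parameters are recovered to 1e−3 relative error; with 8 km positional wander,
18 m GPS noise and 20% dropout the inflection dates are recovered to well
under two days (tested).

The plateau is the interval where the fitted curve is at least 95% of δ
(configurable); its endpoints are found by bisection on the fitted curve and
bound the fixes used for the summer range.

### Migration dates

The four dates are determined from polygon crossings with persistence rules,
not from the curve fit: spring departure is the last fix inside the
non-breeding range before the first excursion that stays outside for at
least `persistence_days` (default 5) and leads to summer arrival; spring
arrival is the first summer-range fix opening at least `persistence_days` of
continuous summer occupancy; the autumn pair mirrors these. Occupancy is
judged at the day level — a day is "in" a range when at least half of its
fixes are inside — because with a 95% isopleth roughly one fix in twenty
falls just outside and fix-level runs would never persist. Emitted records
enforce the ordering invariant departure < arrival < departure < arrival;
any violation voids the autumn pair and is flagged. Residents produce no
dates. The persistence threshold is configurable because no principled
value exists; 5 days cleanly separates foraging excursions (hours to ~2
days) from true departures in this system.

Year assignment: the spring cycle's calendar year indexes the record, and
autumn dates of the same cycle share it. The generator never lets a spring
cross January 1, so continuous day-of-year within the calendar year is an
adequate clock.

## Vegetation phenology

Each region-year of 16-day NDVI composites (23 per year) gets a
double-logistic fit NDVI(t) = vmin + (vmax−vmin)·[logistic(k(t−t0)) −
logistic(k_a(t−t_a))] by bounded least squares from data-driven starts; a
fitted amplitude below 0.05 raises a "no seasonality" signal. Green-up is
the smallest day in the spring window (days 1–180, excluding autumn
crossings) where the curve reaches vmin + 0.5·amplitude. The 0.5 threshold
is the conventional amplitude-threshold definition and the pipeline default.
Noiseless symmetric curves return the midpoint exactly; at 16-day
compositing with noise sd 0.02 the median error is ~1.3 days (tested bound:
4 days).

## Winter climate

For spring year y the winter window is Nov 1 of y−1 through Jan 1 of y,
both endpoints inclusive (62 days) — configurable, since a window ending
January 1 is unusual enough that users may prefer a longer one. Temperature
is the mean over all station-days; precipitation is each station's window
total averaged across stations (a pooled sum would scale with station
count). Missing daily values are excluded, never imputed as zero; exact
duplicate station-day records are dropped so accidental double ingestion
cannot shift a summary.

## Repeatability

r = σ²_b/(σ²_b+σ²_w) from the one-way ANOVA decomposition with the
unbalanced-design group-size correction k₀ = (N − Σnᵢ²/N)/(I−1); a negative
between-individual component is truncated to zero for reporting. Only birds
with more than one year contribute; singletons are dropped and counted. A
REML mixed-model variance ratio is kept as an independent cross-check (the
two coincide on balanced designs; tested to 1e−6).

The permutation test shuffles values across individual labels and reports
p = (1 + #{statistic_perm ≥ statistic_obs})/(1 + n_perm) — the add-one
convention, so p is never zero. The ranking statistic is the *untruncated*
variance ratio: it is continuous under the null, which makes the null
p-value distribution uniform (calibration-tested: KS against U(0,1), and
type-I error at α=0.05 within [0.03, 0.07]); ranking on the truncated r
would pile null p-values at 1 because of the point mass at r=0.

Two modes are reported side by side. Raw r mirrors the classical workflow
(no detrending). The detrended mode removes the shared linear year trend
first: when individuals are sampled in different eras under a strong
population trend — as with staggered multi-year tracking windows — the trend
itself masquerades as between-individual variance and inflates raw r, so the
detrended estimate is the one that recovers the generating variance
partition (the default population's raw r ≈ 0.86 vs. detrended ≈ 0.78 for a
generating 0.76).

## Trend and mixed models

Every model inside a comparison set is fitted by maximum likelihood (not
REML) so AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) is comparable across
fixed-effect structures. k counts every estimated quantity: fixed effects,
the residual variance, the AR(1) coefficient where present, and the
random-intercept variance where present. Where n ≤ k+1 the correction is
undefined; the public `aicc` raises, while model tables carry NaN for such
rows (they sink to the bottom of the ranking instead of aborting a stage).

Cross-sectional analysis fits intercept-only and year-slope means of the
yearly averages with i.i.d. errors and with AR(1) errors — the latter by
exact maximum likelihood (stationary initial condition, Prais–Winsten
transform, ρ profiled numerically), which is cheap at these sample sizes —
and reports all four in one table; the headline slope comes from the
better-supported error structure. Longitudinal candidate sets are
random-intercept models (single ID variance component) with year in every
member: year, year+age, year+covariate, year+age+covariate, and the full
climate model with the temp×precipitation interaction. The detrended set is
{1, dgreenup, dgreenup+age, dgreenup+age+dgreenup:age}, all with (1|ID), on
OLS year-residuals of both the migration date and green-up. Optimizer
failures at the zero-variance boundary fall back to the OLS boundary
solution (re_var = 0, k unchanged) and are flagged; a genuine zero-variance
fit reproduces the OLS log-likelihood to 1e−6 (tested).

One statistical caveat the test suite makes explicit: yearly means of
overlapping multi-year bird cohorts are autocorrelated through the shared
individual effects, so naive i.i.d. OLS confidence intervals on the
cross-sectional slope under-cover on longitudinal populations. The
random-intercept LMM models that dependence and its year-slope CI calibrates
correctly (≥90% coverage over replicate populations, tested); the
cross-sectional CI is calibrated on genuinely cross-sectional (yearly
series) replicates.

## Synthetic-data generator

The generator is the study-design model, not a convenience fixture. Defaults
encode the emulated conditions: 12 residents and 24 migrants over 2002–2011,
hourly fixes, 18 m GPS noise, 20% i.i.d. fix dropout, winter centroid on
the Gulf coast (−91.5, 30.2) and summer centroid in the Northern Great
Plains (−99.5, 47.5) ~2,060 km apart, mean spring departure day 121 (May 1)
advancing −6.44 d/yr, mean autumn departure day 241, migration speed
90 km/day (giving the observed ~3-week spring transit), departure
repeatability target 0.76 with 5-day within-individual sd, NDVI green-up
midpoints advancing −1.61 d/yr, and Gulf-coast-like station weather.
Migrants are tracked 3 consecutive years and residents 2, with start years
staggered across the span as in multi-year capture programmes.

Movement is a deterministic anchor path — winter site, great-circle transit
between the true departure and arrival dates, summer site, return — plus a
mean-reverting (Ornstein–Uhlenbeck) wander with 8 km stationary sd and
1-day relaxation, GPS noise on top, in a local planar frame converted to
lon/lat. This is the minimal structure that produces the double-logistic
NSD shape the migration model assumes. Individual winter sites scatter with
10 km sd for migrants versus 15 km for residents, so migrants winter well
inside the resident-defined non-breeding range.

Timing: spring departure = mean + trend·(year−y0) + individual effect +
within-year noise, with the individual sd chosen so the variance ratio
equals `icc_target`. Arrivals are departure plus a travel time
(distance/speed) carrying its own individual and yearly components; autumn
departure has a small individual sd (2 d) and large within-year sd (12 d).
The default noise split reproduces the qualitative repeatability ordering
reported for this system — spring departure high, autumn arrival and spring
arrival moderate, autumn departure near zero — which arises naturally
because autumn arrival inherits an individual routing component through the
travel time. Mean spring-arrival and autumn-arrival dates are therefore
emergent, not configured. Ordering constraints (departure < arrival within
season, autumn departure ≥ spring arrival + 15 d, autumn arrival ≤ day 360)
are enforced by clipping; springs never cross January 1.

Birds captured immature (<3 yr, 60% of captures) become adults once older
than 3, so the age covariate varies within individuals across years and the
age×year model set is estimable. Sex is carried as a column (80% male among
migrants) but drives nothing.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: behavioural states beyond resident/migrant
(no stopovers, nomadism, dispersal, mortality, or transmitter failure),
spatially explicit NDVI (regional means only; no pixel-level phenology or
the 31.5° N spatial cut, which the pipeline keeps only as a configuration
passthrough), per-bird dropout-rate heterogeneity (a single i.i.d. dropout
probability, where real transmitters ranged from 2 to 24 fixes/day), and
any dependence of timing on the simulated climate series — the generator
deliberately couples migration dates to year only, which is exactly what
makes it the right null instrument for the detrended spurious-correlation
check.

## Determinism and sizes

A single integer seed drives every stage through spawned NumPy generator
streams; two runs under the same configuration are byte-identical, CSVs and
GeoJSON included. Default problem sizes (36 birds, ~840k fixes, 5,000
permutations, 100-replicate recovery studies, 10,000-point isopleth
calibration) were chosen so the complete test suite and the acceptance
script each finish in a few minutes on a single CPU while keeping
Monte-Carlo error far from every asserted tolerance.

## Known limitations

- The persistence-based date rules are validated against the generator, not
  against hand-annotated real tracks; on real data persistent stopovers just
  outside a range boundary would shift detected dates.
- The ANOVA ICC is a point estimate; no parametric-bootstrap CIs or GLMM
  variants for non-Gaussian traits.
- The AR(1)-error option exists only for the cross-sectional yearly series;
  the LMMs assume independent residuals within birds.
- Kernel bandwidth is the scaled reference rule only — no least-squares
  cross-validation, plug-in, Brownian-bridge or autocorrelation-aware
  estimators; with strongly autocorrelated hourly fixes the reference rule
  oversmooths relative to an independence assumption.
- TIMESAT-style envelope iteration and Savitzky–Golay smoothing are out of
  scope; only the double-logistic model class with amplitude thresholding is
  implemented.
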