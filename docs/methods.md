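# Methods

This note documents the models, conventions and numerical choices
behind `migradar`, and what the synthetic-data tests do and do not
demonstrate.

## Solar events and biological periods

Sunrise and sunset come from the NOAA solar-position equations
(low-precision Meeus series evaluated at local solar noon), at the
standard refraction-corrected altitude of −0.833°, with no site
elevation correction; at the study latitudes (~43–45°N) this is
accurate to a minute or two.  Latitudes inside the polar circles are
rejected rather than approximated.

Four periods per solar cycle: dawn = sunrise ± 30 min, day = sunrise
+30 min to sunset −30 min, dusk = sunset ± 30 min, night = sunset
+30 min to the *next* sunrise −30 min.  All intervals are half-open
[start, end), so segmentation partitions the timeline: every in-range
timestamp belongs to exactly one period.  A night is attributed to the
civil date of its dusk, making dusk → night → dawn one migration night.

Two duration bookkeepings coexist deliberately.  The *segmentation
bounds* are physical (night ends before the next day's sunrise), and
these define the effective-hours denominators of passage rates.  The
*nominal per-cycle durations* (`SolarDay.period_durations`) use the
same date's sunrise/sunset only (night = 24 h − day − 2 h) and sum to
exactly 24 h; these match how season summaries conventionally print
day/night lengths.  The two differ by the day-to-day sunrise drift,
under 2 min at temperate latitudes in spring.

## Records, filters and passage rate

Track tables are pandas DataFrames with a fixed schema per antenna
(one row per tracked target); timestamps are stored UTC, and "daily"
aggregation keys to local civil time (fixed UTC−4, the study region's
season offset).  Record-level filters are idempotent and commute:

* track length — fewer than 5 radar returns is noise, dropped;
* standard front — VSR targets with |offset| ≤ 500 m are kept
  (closed boundary at exactly ±500 m);
* over-water — HSR targets strictly west of the site's shoreline
  longitude threshold;
* exclusion mask — rain/contamination intervals, half-open, merged
  when overlapping; excluded time is subtracted from the
  effective-hours denominator of the affected period instances, and a
  fully excluded instance is omitted (not recorded as zero).

Unparseable rows fail fast by default because silently dropped rows
would bias passage rates; a skip-with-log mode exists for exploratory
work.

TPR = target count / effective hours per period instance.  Dawn and
dusk are exactly one hour, so their TPR equals the count when nothing
is excluded.  Percent shoreline excess is computed per paired instance
as (shore − inland)/inland, then averaged with its SE across instances
(the same unit of replication the regression uses); inland-zero
instances are dropped with a warning rather than producing infinities.

## Least-rectangles regression

Both TPR series measure the same latent migration intensity, so the
regression treats the axes symmetrically ("least rectangles").

* **gaussian** — the geometric-mean / reduced-major-axis line:
  slope = sign(r)·s_y/s_x, intercept = ȳ − slope·x̄.  Exact closed
  form; swapping axes maps (b, a) → (1/b, −a/b) identically.
* **poisson** (default) — an errors-in-variables likelihood for
  counts: per point a free latent mean μᵢ with xᵢ ~ Pois(μᵢ),
  yᵢ ~ Pois(a + bμᵢ).  For fixed (a, b) the optimal μᵢ solves a
  per-point quadratic, including the rate-zero boundary for zero
  counts, so the profiled likelihood is evaluated in closed form; the
  two parameters are then maximised by L-BFGS-B in (a, log b) with an
  analytic envelope-theorem gradient, started from the gaussian fit.
  Zero-count points kink the profile at a = 0; when the quasi-Newton
  step stalls there (detected by a non-negligible gradient at the
  returned point) a Nelder–Mead polish finishes the climb.  The model
  is symmetric under axis exchange up to optimizer tolerance (~1e-6).
* **sqrt_gaussian** — a sensitivity alternative: gaussian family on
  variance-stabilised √counts, slope reported as the squared
  √-scale slope.

Uncertainty is a seeded non-parametric bootstrap over (x, y) pairs
(default B = 2000; percentile CIs).  Degenerate resamples (zero
variance on an axis) are redrawn and counted.  The identity-line
decision — "does the 95% confidence region include y = x?" — is made
jointly: the reference point (1, 0) is compared against the
Mahalanobis 95% contour of the bootstrap (slope, intercept) draws,
with the fraction of draws at least as extreme reported as a p-value
proxy, plus marginal CI exclusion flags and a pointwise fitted-value
envelope for plotting.  The test refuses to run on fewer than 100
draws.  Simulation shows the joint rule holds its nominal 5% size for
well-behaved designs of n ≳ 200 points; at a few dozen points the
pairs bootstrap is mildly anti-conservative (a known small-sample
property), which is why the test suite calibrates it at n = 200.

## Circular statistics

Compass convention is fixed project-wide: a heading θ maps to the unit
vector (sin θ, cos θ) so that 0° = north and angles ascend clockwise;
the circular mean is atan2(mean sin, mean cos) mapped back to compass
degrees, and the mean resultant length (MRL) is the mean vector's
length.  MRL below 1e-12 marks the mean undefined.  The night→dawn
shift is wrap(mean_dawn − mean_night) to (−180°, 180°], positive =
clockwise; +180° is the chosen image of an exact reversal.

The two-sample Watson–Williams test uses the classical
high-concentration F approximation with the 1 + 3/(8κ̂) correction;
κ̂ inverts A(κ) = I₁/I₀ at the weighted within-sample MRL via the
standard three-branch rational approximation.  The comparable-
concentration assumption is checked and logged, not enforced: at the
sample sizes involved the magnitude of the direction shift, not the
p-value, carries the biological signal, and reports always print the
shift and MRLs alongside F and p.  Subsampling to equal group sizes is
simple random sampling without replacement, seeded, with seeds echoed
into the output tables.

## Synthetic seasons

The generator draws, per night, a mean-one multiplier (a log-normal
pulse magnitude with a per-night pulse probability and a quiet-night
floor) shared by both sites — the sporadic, spiky structure of real
migration seasons.  Per period instance, the post-filter front count
is Poisson with mean = base rate × nightly multiplier × period factor
× (shoreline multiplier if shoreline) × effective hours; filter fodder
(targets outside the front at equal areal density, sub-5-observation
tracks, HSR double counts with jittered position/heading) is layered
on top so the filters have real work to do.  Ground truth (multipliers,
nightly intensities, mixture means) is emitted alongside every dataset.

Defaults are anchored to the observed conditions of a Great Lakes
spring season: inland night base rate 517 targets/h (putting the pooled
shoreline+inland night mean near 545/h), period rate factors
dawn 0.206 / day 0.070 / dusk 0.064 relative to night (the ratios of
the observed per-period hourly means), shoreline multipliers
dawn 2.32 / day 1.35 / dusk 1.37 / night 1.11, and heading mixtures
whose means rotate clockwise from night to dawn by ~11° inland, ~31°
at the shoreline and 343°→35° (+52°) over water.  Night headings are
two-lobed von Mises mixtures (north + northwest), reproducing the
moderate MRLs (~0.4–0.6) seen in real rose diagrams at realistic
concentrations.

What the generator does *not* model: wind drift and altitude-dependent
headings, weather beyond exclusion-mask fixtures, spatially varying
detection probability, VSR double-counting, or target identity across
antennas.  Passing recovery tests therefore demonstrates that the
estimators are correct for the assumed data-generating process, not
that the assumptions hold for any particular radar deployment.

## Problem sizes and determinism

Monte-Carlo checks in the test suite are scaled to a single CPU: CI
coverage uses 200 replicates at 40 points with B = 200; the
identity-line size check uses 200 replicates at 200 points with
B = 400; Watson–Williams size uses 1000 replicates of 500 + 500
headings.  The acceptance script simulates 48 nights (about the pooled
span of the three migration-season trials) for activity and slope
summaries, 7 nights for the side-by-side radar comparison, and 12
higher-volume nights for the direction analysis with subsamples of
3000 headings per group.  Every random draw — generator, bootstrap,
subsampling — flows from explicit seeds, and identical seeds reproduce
tables byte-for-byte.

## Known limitations

* The poisson-family estimator assumes pure Poisson dispersion; real
  hourly counts are often overdispersed, which widens true sampling
  error relative to the model (the non-parametric bootstrap absorbs
  this for CIs, but the point estimator is no longer ML-efficient).
* The Watson–Williams approximation degrades for MRL ≲ 0.3 or very
  unequal concentrations; it is logged, not blocked.
* The bootstrap resamples period instances (or paired hours)
  independently, ignoring night-to-night autocorrelation.
* Fixed UTC−4 local time is correct for a single-season Great Lakes
  study but not DST-transition-safe for year-round use.
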