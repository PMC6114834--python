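# migradar

Analysis of bird and bat migration from avian radar track tables:
do migrants concentrate along a lakeshore, and do nocturnal migrants
caught over open water turn back toward land at first light?

`migradar` is built for movement ecologists working with paired radar
deployments (one unit near a shoreline, one inland).  Each radar unit
carries two antennas: a vertical scanning radar (VSR) whose per-target
counts index activity, and a horizontal surveillance radar (HSR) that
records each target's compass heading.  The package takes per-target
track tables (CSV/XLSX), applies the standard record-level filters,
segments time into solar-defined biological periods, and answers the
two questions above with a symmetric slope test and circular statistics.

## What it computes

**Target passage rate (TPR).**  Targets per hour crossing a 1-km-wide
vertical "standard front" (±500 m along the VSR scan plane), the radar
analogue of migration traffic rate.  Time is segmented into four
biological periods from NOAA sunrise/sunset: dawn and dusk are the
hours centred on sunrise and sunset, day and night fill the gaps.  The
unit of observation is the *period instance* (site × date × period).

**Least-rectangles slope test.**  Shoreline TPR (y) is regressed on
inland TPR (x).  Neither series is a "predictor" — both are noisy
measurements of the same migration intensity — so the line is fitted
symmetrically in both errors.  The gaussian family is the classical
geometric-mean (reduced major axis) line, slope = sign(r)·s_y/s_x.  The
default poisson family suits count-like rates: each point carries a
latent intensity μᵢ with x_i ~ Pois(μᵢ), y_i ~ Pois(a + bμᵢ); the μᵢ
are profiled out in closed form and (a, b) maximised numerically.  A
seeded non-parametric bootstrap over (x, y) pairs gives percentile CIs,
and the line differs from parity when the joint 95% bootstrap region of
(slope, intercept) excludes (1, 0) — the line y = x.  A slope of 1.27
means 27% more activity at the shoreline.

**Dawn reorientation.**  Compass headings (0° = north, clockwise) are
compared between night and dawn per location (inland, shoreline, and
the over-water subset west of the shoreline longitude) with equal-size
seeded subsamples, the Watson–Williams F test, and the signed circular
shift wrap(mean_dawn − mean_night) ∈ (−180°, 180°], positive =
clockwise.  A large positive over-water shift is the signature of
migrants turning back toward land at first light.

A seeded synthetic-season generator (`migradar.simulate`) emulates the
whole data-generating process — sporadic nocturnal pulses, per-period
shoreline multipliers, von Mises heading mixtures that rotate clockwise
at dawn, detection geometry and double-counting — so every stage of the
pipeline is testable against known ground truth.

## Worked example

Fit the dawn-period slope on simulated paired rates whose true
shoreline multiplier is 2.32:

```python
import numpy as np
from migradar import LeastRectangles

rng = np.random.default_rng(0)
mu = np.exp(rng.uniform(np.log(20), np.log(600), 48))   # latent intensity
inland = rng.poisson(mu).astype(float)                   # inland TPR
shore = rng.poisson(2.32 * mu).astype(float)             # shoreline TPR

res = LeastRectangles(shore, inland, family="poisson").fit(
    bootstrap=1000, seed=42)
print(res.summary())
```

```
Least Rectangles Regression Results
==============================================
family:            poisson
n points:          48
bootstrap draws:   1000 (seed 42)
----------------------------------------------
slope:             2.3313
intercept:         -2.3886
slope 95% CI:      (2.2591, 2.4031)
intercept 95% CI:  (-13.2234, 6.6052)
y = x line:        excluded from joint 95% region (p-proxy 0.000)
==============================================
```

The slope estimate 2.33 recovers the generating multiplier 2.32; its CI
excludes 1 and the joint region excludes the 1:1 line, so shoreline
activity is significantly higher.  `res.identity_line_test()` and
`res.fitted_envelope()` expose the decision rule and the plotting band.

The end-to-end surface is the CLI:

```bash
migradar simulate --seed 1 --out data/
migradar compare-trials --config data/sites.yaml --data-dir data \
    --seed 1 --bootstrap-B 2000 --out report/
migradar directions --config data/sites.yaml --data-dir data \
    --seed 1 --subsample-n 3000 --out report/
```

which writes tidy CSVs (per-period slopes and CIs, TPR summaries,
Watson–Williams tables, rose-diagram wedge counts, fitted envelopes)
plus a JSON run summary.

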