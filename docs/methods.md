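# Methods

`terratactics` turns minute-resolution GPS focal-follow tracklogs of two
neighboring chimpanzee groups into three statistical analyses of
territorial tactics: the likelihood of stopping on peripheral hills, the
modulation of activities by elevation and territory location, and
post-stop advance/retreat decisions toward rivals.  This note documents
the models, their assumptions, the tunable parameters, the synthetic-data
generator, and the numerical choices — in that order.

## Landscape reconstruction

Elevation is estimated only from the tracklogs themselves: handheld GPS
units record elevation once per minute, and repeated traversals of the
same ground give several readings per ~10 m patch.  Fixes are assigned to
a square lattice anchored at the arithmetic center of all fixes
(bin size 10 m, matching typical handheld accuracy under canopy), each fix
joining the bin whose center is nearest; the cell estimate is the median
of its readings, which is robust to the ±10–13 m scatter of individual
readings.  Ties in nearest-center assignment (exact half-bin positions)
go to the lower index, so binning is deterministic.

**Peripheral hills** are connected components, under single linkage at
≤ 50 m between cell centers, of cells at or above the elevation threshold
(default 230 m, the preset for the 99th percentile of the reconstructed
range; a percentile-based threshold is available via
`RunConfig(hill_elev_threshold=None)`).  Single linkage is chosen because
ridge lines connect supra-threshold cells in chains.  The summit is the
highest member cell; equal-elevation ties resolve to smallest y then
smallest x.  The percentile is computed over *bins*, not raw fixes, so
heavily revisited ground is not over-weighted (configurable).

**Low rest locations** are stationary segments (≥ 5 min within 25 m)
inside the inter-group overlap band whose reconstructed elevation is at
most 180 m, merged by single linkage within 50 m.

## Territory model

Each group's utilization distribution (UD) is a fixed-bandwidth isotropic
Gaussian kernel density estimate over its fixes, `h = 149` m (a plug-in
scale appropriate for forest chimpanzee ranging; a plug-in estimator is
not re-run — the bandwidth is part of the study conditions).  The KDE is
evaluated by binning fixes on a 25 m lattice and convolving with a
Gaussian of SD `h`, the standard fast equivalent of the exact KDE when the
lattice is much finer than the bandwidth; the surface is normalized to
unit volume.

The **kernel value** of a location is the smallest k ∈ 1..99 such that the
location lies inside the k%-volume contour:
`ceil(100 × volume{density ≥ density(x)})`, clamped to [1, 99].  Kernel 1
is the most central, heavily used ground; values ≥ 75 are treated as the
territory periphery.  Percent-volume contours are extracted as iso-density
polygons; the **territory center** is the UD mode (a mean-of-fixes variant
exists), and the yearly territory size is the area of that year's 95%
contour.  The **relative distance to center** covariate divides the
distance to the center by the equivalent-circle radius `sqrt(area/π)` of
the yearly 95% area — radius rather than area keeps the covariate
dimensionless and in distance units; both normalizations are implemented.

The **overlap band** spans from the eastern group's westernmost visited
x-coordinate to the western group's easternmost; hills are restricted to
the band by a cell mask.

## Event extraction

All rules operate on fixes annotated with reconstructed (bin-median)
elevation:

* **visit** — a maximal interval within 50 m of a site's summit with
  reconstructed elevation within ±13 m of the summit elevation (the upper
  bound of observed within-bin variation; this gate excludes travel past a
  cliff base below the summit).  Same-site visits separated by < 5 min
  merge.
* **stop** — some window of consecutive fixes spanning ≥ 5 min in which
  every fix stays within 25 m of the window's first fix; the threshold is
  below GPS accuracy plus small drift.  `stop_minutes` is the longest such
  window.
* **direction before arrival** — change over a 30-min lookback on the
  center–border axis.  The default metric is the radial distance to the
  territory center with a 100 m dead-band.  A kernel-value-change variant
  (dead-band 5 kernel units) is provided, but it is not the default:
  reconstructed UDs develop local density maxima on heavily dwelt-on
  hills, so the kernel value *drops* on arrival at a well-used hill
  regardless of approach geometry, which confounds the direction signal.
  The radial metric is monotone on the center–border axis by construction.
  Changes inside the dead-band are `ambiguous` and excluded from the stop
  model.
* **departure** — first fix beyond 50 m of the site with no re-entry
  within 5 min.
* **advance/retreat** — with the closest rival party's position frozen at
  departure time, `d0` the distance at departure and `d1` the distance 30
  min later (or at track end, with ≥ 5 min of track required):
  advance if `d0 − d1 > 50` m, retreat if `d1 − d0 > 50` m, otherwise
  undetermined and excluded.  A minimum-distance-in-window variant is
  available (`statistic="min"`).
* **intercommunity distance** — per-minute distance to the closest rival
  party; averaged over the use interval for the stop model, taken at
  departure for the advance model.  **Imbalance of power** is the own
  adult party size minus the aggregated rival adult count observed in the
  preceding 30 min.  Missing rival data drops the row (counted, never
  imputed).

Hill counts before/after are positional: the k-th of n same-day hill
visits has k−1 before and n−k after; low-location rows count surrounding
hill visits.

## Statistical models

All three analyses are binomial GLMMs with a logit link, random
intercepts, and maximum-likelihood fitting via the Laplace approximation
(`glmm` module; no Python package in the scientific stack provides this,
so the fitter is implemented here and cross-checked against an external
mixed-model backend in the test suite, agreeing to ~1e-4 on fixtures —
well inside the |Δβ| ≤ 0.02 interchange tolerance).

* **stop model** — response: stop at a hill visit (0/1); test predictors:
  direction (border = 1), hills before, hills after, own adult party size,
  intercommunity distance, and party-size × distance; controls: relative
  center distance and its square, kernel value, elevation, time of day,
  sex, group; random intercepts: hill, date:group, focal.
* **activity models** — one model per activity (rest/feed/travel as 0/1)
  on minute points thinned to 30-min spacing per day (about twice the mean
  activity-bout length, so neighboring kept points come from different
  bouts); test predictors: kernel value, elevation, and their interaction;
  controls: sex class (male / female / oestrus female), group, seasonal
  sine/cosine of day-of-year (angle `2π·doy/365.25`), party size, monthly
  food availability, oestrus-female count; random intercepts: date:group
  and focal.
* **advance model** — response: advance toward rivals (0/1) after a
  peripheral stop (hills and low locations pooled); test predictors:
  direction (numeric), hills before/after, elevation, imbalance of power,
  ln intercommunity distance at departure, and the two- and three-way
  interactions of elevation × imbalance × ln distance; controls and
  randoms as in the stop model (elevation is a test predictor here).

Continuous covariates are z-scored to mean 0, SD 1 using the modeling
table's own moments after row exclusions; the natural log of
intercommunity distance is taken before z-scoring (short distances carry
more information about detectability).  Interactions are products of the
z-scored main effects.  The quadratic center-distance control is the
square of the z-scored distance.

Fitting is two-stage and deterministic: a fast profile over the
random-effect SDs with fixed effects folded into the inner penalized
Newton step, then a joint refinement of (β, σ) against the Laplace
objective (inner convergence at relative log-likelihood change < 1e-8;
random effects start at zero).  σ is parametrized on its natural scale
with a [0, 15] box, so a zero variance is an ordinary boundary point;
single-level random factors are dropped.  Separation is detected from the
linear predictor (|η| > 30 with diverging coefficients), not from
coefficient magnitude alone, because near-collinear seasonality columns
legitimately produce large coefficients.

Inference: the full model is compared with a controls-plus-randoms null by
likelihood-ratio test; per-term p-values come from single-term deletions
(`drop1`) respecting marginality (no main effect leaves while its
interaction stands); model reduction removes nonsignificant interactions
highest-order first, refitting after each removal, and never touches main
effects or controls.  Wald z and normal CIs are reported for table parity;
parametric-bootstrap percentile CIs are available.  Effect sizes use the
Nakagawa decomposition for the logit link: marginal
R² = var(Xβ)/(var(Xβ) + Σσ² + π²/3); conditional R² adds Σσ² to the
numerator.  VIFs come from the main-effects-only linear design;
overdispersion is the Pearson χ²/df with conditional fitted values; model
stability refits leaving out each random-effect level in turn.

## Temporal autocorrelation term

Minute- and event-level observations are serially dependent.  Residual
diagnostics report, per pairing unit, the Pearson correlation between
pairwise |Δresidual| and pairwise time lag (temporal) or metric distance
(spatial); the pairing unit defaults to day:group for the diagnostics
because all-pairs across a multi-year study is quadratic, while the
correction term itself pairs across the whole study within group.

The correction term for row i is the Gaussian-weighted average of all
*other* same-group response-scale residuals,
`value_i = Σ_j φ(t_i − t_j; σ) r_j / Σ_j φ(·)`, computed from the model
*without* the term (one-shot; an optional single re-iteration exists).
Time is absolute minutes, so within- and across-day lags both contribute.
The weighting SD σ is chosen by maximizing the refit model's likelihood
over a log-spaced grid (default 5 min–24 h, 25 points) with a bounded
golden-section refinement between the best grid point's neighbors; the
z-scored term enters as a fixed effect and is treated as a control.

**A calibration caveat that shapes the CI convention.**  The AC covariate
is a *generated regressor*: it is a function of the same data's
residuals.  Under serial independence its Wald z-statistic is
over-dispersed (SD ≈ 1.5 rather than 1: each residual appears in many
rows' terms, roughly doubling the score variance) and acquires a negative
bias as σ grows (ML residuals sum to ≈ 0, so near-uniform weights turn
the term into a negative copy of the own residual), on top of the
selection effect of maximizing over σ.  Plain Wald CIs for this one
coefficient are therefore anticonservative.  The package's calibrated
interval, `autocorr.bootstrap_ci_ac`, is a procedure-level parametric
bootstrap: each replicate simulates the response from the AC-inclusive
fit, refits the base model, rebuilds the weighted-residual term from the
replicate's own residuals at the selected σ, and refits — capturing the
generated-regressor variance.  Its measured null coverage is ≈ 92–93%
(the acceptance suite checks ≥ 90%); Wald CIs for the AC term are still
printed for table parity but should not be used for inference.

## Synthetic data generator

The generator (`simdata`) realizes the statistical structure the analysis
assumes; it makes no attempt to model cognition.  Defaults define the
study conditions and are not tuned per run:

| parameter | default | meaning |
|---|---|---|
| arena | 8,000 × 9,000 m | two territories plus overlap band |
| band | x ∈ [3,000, 5,000] m | ~2,000 m West–East overlap |
| base elevation | 190 m ± ~8 m ripple | low-relief forest plain |
| inselbergs | 12 in band + 6 outside, summits 242–287 m, bump SD 45 m | peripheral hills |
| low sites | 8 depressions, −25 m, SD 160 m | rest locations ≤ 180 m |
| study | 60 follow days, spaced 5 calendar days, 600 min/day, 1 fix/min | ~72,000 fixes |
| GPS noise | 5 m horizontal, 3 m vertical | handheld accuracy |
| speed | 45 m/min | party travel speed |
| bout means (min) | rest 11.6/15.07, feed 16.46/17.66, travel 5.61/7.15 per group | activity process |
| patrol probability | 0.6/day | border excursion days |
| stop logit | β₀ = −0.9, β_dir = 1.6, β_after = −0.4, hill-intercept SD 0.5 | stop decisions |
| advance logit | γ₀ = −0.35, β_imb = 0.5, β_dist×elev = 0.4, β_dir = 0.75 | post-stop decisions |

Days are either ranging days (waypoint drift near the territory center
plus an activity-bout process without self-transitions, so observed runs
equal generated bouts) or patrol days (a waypoint route out through the
band visiting 1–5 hills ordered toward the border, an optional low-site
rest, an optional revisit on the return leg).  Both groups move in one
joint minute loop: at each stop's departure the rival group's true
position and adult count are read off directly, the advance draw is made
on fixed nominal covariate scales (imbalance / 3, (ln d − ln 1500)/0.8,
(elev − 195)/35), and a 30-min maneuver toward or away from the frozen
rival position follows.  Truth direction labels come from the *realized*
motion (radial rule on true positions), so the emitted labels are
consistent with the emitted tracklogs by construction.  All draws flow
from `default_rng([seed, day])` substreams; a fixed seed is byte-identical.

What the generator emulates: two-group geometry, revisit accumulation on
a 10 m lattice, fission–fusion party-size drift, logistic stop/advance
decisions with a hill random intercept, activity bouts with the field's
mean lengths.  What it does not emulate: GPS dropout and multi-observer
duplication, canopy-biased elevation error, true fission into multiple
simultaneous parties per group, hunts/intergroup encounters, and any
goal-directed cognition.  Passing tests therefore demonstrate that the
pipeline recovers the *assumed* structure at field-realistic noise — not
that real chimpanzee data satisfy those assumptions.

One scale consequence worth knowing: the pipeline's stop model conditions
on more structure (date:group and focal intercepts, spatial controls)
than the generating logit, so its direction coefficient sits above the
generating 1.6 on the conditional scale (logit non-collapsibility).  The
estimator itself is unbiased: refitting with the generating structure
recovers 1.6 to < 0.01 on average over 100 replicates (acceptance suite).

## Problem sizes and runtimes

The test suite and acceptance script run on one CPU: the end-to-end
consistency check uses a 20-day study (~24,000 fixes), parameter-recovery
loops use 100 replicates of 717 visits, null calibrations use 200 (drop1)
and 30 (AC bootstrap) replicates, and the acceptance script runs the full
60-day study.  These sizes give stable rates (binomial SE ≤ ~2 points on
any reported percentage) while keeping the whole suite around ten minutes.

## Known limitations

* Coordinates must arrive in projected meters; no CRS handling is built in.
* The Laplace approximation shares lme4's small-cluster bias for binary
  responses with few observations per random-effect level; adaptive
  quadrature is not implemented.
* `kernel_value` resolves at the 25 m evaluation lattice; kernel values of
  points between lattice nodes use the nearest node's density.
* The kernel-delta direction rule is retained only as an option; see the
  event-extraction section for why it is confounded on usage-weighted UDs.
* Real supplementary per-event tables can be loaded and modeled through
  the same `glmm` specs, but the package ships no copy of them; all tests
  run on synthetic data.
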