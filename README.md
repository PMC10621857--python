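# terratactics

Territorial tactics from GPS focal-follow data: do animals in two
neighboring groups use high ground strategically when operating near a
contested border?

The package implements, end to end, the analysis pipeline for
minute-resolution tracklogs of two neighboring chimpanzee communities
sharing a territory overlap zone:

1. **Landscape reconstruction** — fixes are binned on a 10 m lattice
   anchored at their arithmetic center; per-cell median elevations give a
   terrain raster from which *peripheral hills* (cells ≥ 230 m, the 99th
   percentile of the range, single-linkage merged within 50 m, restricted
   to the inter-group overlap band) and *low rest locations* (≤ 180 m) are
   derived.
2. **Territory model** — a kernel utilization distribution (isotropic
   Gaussian KDE, h = 149 m) per group; every location gets a *kernel
   value* k ∈ 1..99, the smallest percent-volume contour containing it
   (1 = territory core, ≥ 75 = periphery); percent-volume contours,
   territory center, yearly 95%-contour areas, and the West–East overlap
   band between the groups' extreme opposing excursions.
3. **Event extraction** — hill/low-site visits (within 50 m at matching
   elevation), stop events (≥ 5 min pause), pre-arrival travel direction
   on the center–border axis, departures, and post-stop advance/retreat
   relative to the closest rival party's position at departure, plus
   intercommunity distances and the imbalance of power (own minus rival
   adult count).
4. **Statistical models** — binomial-logit mixed models (random
   intercepts for location, date:group, and focal; maximum likelihood via
   the Laplace approximation, implemented in-package and cross-checked
   against an external mixed-model backend), with full-vs-null
   likelihood-ratio tests, `drop1` per-term LRTs, interaction-pruning
   model reduction, Nakagawa R², VIFs, parametric-bootstrap CIs,
   leave-one-level-out stability, and overdispersion checks.  For the
   stop model the response is

   logit P(stop) = β₀ + β₁·direction + β₂·hills_before + β₃·hills_after
   + β₄·party + β₅·distance + β₆·party×distance + controls + u_hill +
   u_date:group + u_focal,

   with all continuous covariates z-scored.
5. **Temporal autocorrelation term** — each row receives a
   Gaussian-weighted average of the other same-group model residuals,
   with the weighting SD chosen by maximizing the refit likelihood; a
   procedure-level parametric bootstrap provides a calibrated CI for this
   generated regressor.
6. **Synthetic study generator** — a two-group fission–fusion movement
   simulator over an inselberg-studded landscape with logistic stop and
   advance/retreat decisions at known coefficients, so every pipeline
   stage has a recoverable ground truth without any field data.

Intended users: movement ecologists and biostatisticians who want either
the full pipeline (tracklogs in, model tables out) or the individual
pieces (the terrain binning, the kernel-value machinery, the Laplace
GLMM, the autocorrelation term) with a tested synthetic ground truth.

## Worked example

Simulate the default two-group study (60 follow days, 600 min/day,
1 fix/min), run the pipeline, and fit the stop model:

```python
from terratactics import simdata, pipeline, glmm

bundle = simdata.gen_tracklogs(simdata.SimConfig(seed=1))
land   = pipeline.extract_landscape(bundle.fixes)
ev     = pipeline.extract_events(bundle.fixes, bundle.party_obs,
                                 bundle.minutes, land)
stop   = pipeline.run_stop_analysis(ev.stop_table)
```

This prints (seed 1):

```
peripheral hills: 12 | band width: 3676 m | hill visits: 250
                                 estimate     se      z
(Intercept)                        -2.696  0.614 -4.394
direction_border                    2.255  0.602  3.744
n_hills_before                     -0.242  0.295 -0.820
n_hills_after                      -0.378  0.182 -2.077
adult_party_size                    0.222  0.155  1.429
intercomm_dist                     -0.059  0.156 -0.376
adult_party_size:intercomm_dist     0.251  0.160  1.567
...
full-null LRT: chi2 = 30.21, df = 6, p = 3.6e-05
drop1 p (direction): 1.581e-05
marginal R2 = 0.273, conditional R2 = 0.273
```

Reading the output: the 12 detected hills are the generator's 12 in-band
inselbergs; stopping is far more likely when the party was traveling
toward the border (`direction_border`, fitted 2.26 ± 0.60 against a
generating coefficient of 1.6 on the sparser generating scale — the
richer fitted model sits on a steeper conditional-logit scale), and less
likely the more hills remain ahead that day (`n_hills_after`,
−0.378 ± 0.182, generating −0.4 per hill times the covariate's SD).  The
full-null LRT shows the six test predictors jointly matter; the party ×
distance interaction does not (drop1 p ≈ 0.34) and would be removed by
`pipeline.run_advance_analysis`-style reduction.

The same bundle drives the advance model with its three-way
elevation × imbalance × ln-distance interaction and the autocorrelation
term (`pipeline.run_advance_analysis(ev.advance_table)`), and the
activity models
(`pipeline.run_activity_analysis(pipeline.annotate_minutes(bundle.minutes,
bundle.fixes, land))`).

A command-line surface wraps the same calls:

```bash
terratactics simulate --seed 1 --days 60 --out bundle/
terratactics run --fixtures bundle/ --out results/
```

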