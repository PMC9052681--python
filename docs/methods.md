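# Methods

This note records the models and procedures the package implements, the
defaults it chooses where the underlying study protocol leaves room, and what
the synthetic-data tests do and do not demonstrate.

## Time and geometry

All timestamps are stored tz-aware in UTC. Calendar-day quantities (daily
presence, residence index, day bins) apply a fixed configurable offset,
default **+03:00** (local time at the study site); the day boundary is not
part of the original protocol description, so it is a config knob
(`tz_offset_hours`). Tied timestamps sort by `(tag_id, timestamp,
receiver_id)` so every pipeline stage sees a total order.

Distances use a spherical Earth, R = 6,371 km. Over the 1–125 km scales of
receiver spacing the sphere-vs-ellipsoid error is metres and irrelevant next
to the 540 m detection range. Planar work (kernel densities) uses an
azimuthal equidistant projection about the data centroid, which keeps radial
distances exact; over a bay spanning under a degree the angular distortion is
negligible.

## Detection QC

Three filters run in a fixed order — isolated singles, post-release, speed —
and the sequence is **iterated to a fixed point**. A single pass is not
idempotent: removing a record can leave its only companion newly isolated
(measured at one to two records per ~20,000 on synthetic data). Iterating
restores the invariant that re-filtering filtered data removes nothing, while
each record is still attributed to exactly one removing stage, so the
conservation identity `raw = singles + post_release + speed + retained` holds
exactly.

* *Isolated singles*: a detection with no same-tag companion at any receiver
  within ±60 min is treated as a decoding artefact. The window is a config
  knob (the protocol does not define "isolated"); ±60 min matches the event
  timeout used elsewhere in the analysis. Offshore regions are exempt: tag
  density there is too low for code collisions, so lone detections are
  credible.
* *Post-release*: strictly earlier than release + 48 h, on exact timestamps,
  not calendar days.
* *Speed*: scanning each tag's chronological sequence, a detection at a
  different receiver than the last survivor implying a straight-line speed
  above 2 m/s is dropped, and the scan re-evaluates the next record against
  the survivor. Same-receiver pairs are never dropped (zero implied
  distance), which means an A→B→A sequence with a fast middle hop loses only
  B. Dropping the *later* record preserves already-validated track history;
  `speed_drop: both` is available. The scan is proven equivalent to a
  subset-enumeration oracle (the prefix-greedy maximal consistent keep-set)
  on thousands of random sequences.

Daily presence requires **two** retained detections of an animal within one
local calendar day.

## Residency metrics

* RI = distinct detection days / track days, with track days counted
  first-to-last detection day inclusive (`last − first + 1`); this
  convention reproduces the published per-animal ratios (e.g. 352/702 →
  0.50) and the exclusive variant is a config flag.
* Residency events open on the second consecutive detection at the same
  receiver with gap < 60 min; an intervening other-receiver detection resets
  the candidate; events end at their last member detection. Equivalence with
  an independently coded run-grouping oracle is tested on random sequences.
* Maximum non-residence is the longest run of absent days strictly between
  two present days — leading/trailing absence does not count.
* Minimum distance sums great-circle hops between consecutive
  distinct-receiver detections; it is a lower bound by construction.
* Networks count directed transitions between distinct receivers;
  zero-detection receivers are carried as isolated nodes; an undirected
  collapse is provided for plotting.
* Group comparisons use Welch's unequal-variance t-test on RI by sex and
  Pearson correlations of wingspan against detections and RI, with
  Shapiro–Wilk and Levene diagnostics reported alongside. Degenerate groups
  (n < 2 or zero variance) are flagged and skipped.

## Hourly presence GAMM

The model is a binomial GAMM with logit link fitted as a penalized GLM:

`logit P(y=1) = β₀ + f_Day(doy) + f_Hour(hour) + f_Moon(moon) + f_CHLA(chla)
+ sex + maturity + β·nStations + u_animal`

* **Bases.** Day-of-year and hour use cyclic cubic regression splines
  (k = 7) in the value-at-knot parameterisation: second derivatives at the
  knots are the linear map `B⁻¹D·β` implied by spline continuity, the
  penalty `D'B⁻¹D` is exactly the integrated squared curvature, and value,
  first and second derivative match at the period ends. Moon (k = 6) and
  chlorophyll-a (k = 7) use the natural (second-derivative-zero at the
  boundary) analogue with quantile-placed knots. Both bases are verified
  against `scipy.interpolate.CubicSpline` with periodic/natural boundary
  conditions and against numerical quadrature of ∫f″².
* **Identifiability.** Each smooth absorbs a sum-to-zero-over-data
  constraint via a Householder null-space reparameterisation; penalties are
  rescaled to unit mean diagonal so one λ grid serves every term.
* **Random intercept.** Per-animal dummies under a ridge penalty with its
  own λ — the standard mixed-model-as-penalized-GLM equivalence.
* **Fitting.** Penalized IRLS with step-halving on the *penalized* deviance
  (plain deviance descent is wrong under warm starts across λ values);
  convergence on relative penalized-deviance change < 1e-9, cap 100
  iterations; fitted probabilities clipped away from 0/1 and near-boundary
  fits flagged as possible separation.
* **Smoothing selection.** Coordinate-wise search per penalized block over a
  log-spaced λ grid (default 10⁻² … 10⁶), minimising GCV
  `n·deviance/(n − edf)²` with warm-started refits; `sweeps` controls the
  number of coordinate passes. This is deliberately simpler than full REML
  and is documented as such; in the λ→0 limit the fit reproduces an
  unpenalized GLM (checked against statsmodels).
* **AIC.** Conditional: deviance + 2·edf with edf = tr[(X'WX+S)⁻¹X'WX].
  Model selection fits all 2⁴ subsets of the four smooths (parametric terms
  and random intercept always included) and ranks by this AIC; failed
  candidates are recorded and ranking proceeds over successes. Because AIC
  variants and basis parameterisations differ across implementations, the
  published deviance-explained figure is not a reproduction target.
* **Covariates.** Day-of-year uses a fixed 365-day cycle with Feb 29 folded
  onto Feb 28. nStations is the hourly count of receivers with an active
  interval covering the hour, entered linearly. Environmental gaps are
  forward-filled with a warning up to a 7-day tolerance, then error.
* Partial effects are reported centred (sum-to-zero over observed covariate
  values) with Bayesian-covariance standard errors; per-term p-values are
  Wald chi-square statistics on the term's coefficients with df = term edf —
  approximate, as in any penalized-likelihood summary.

## Space use

Centers of activity are detection-count-weighted mean receiver positions per
animal per 6-h bin (12-h for geolocation), bins aligned to local midnight;
empty bins produce no COA. Monthly kernel utilization distributions pool
COAs across animals and years: a bivariate Gaussian product kernel with the
reference bandwidth `h = σ̂·n^(−1/6)`, `σ̂` the mean of the two coordinate
standard deviations, evaluated on a 100×100 grid padded by 3h around the COA
bounding box. The gridded cell masses are **normalized to sum exactly to
one** — contour levels and areas are defined on this gridded mass, so the
mass-conservation and 50%⊆95% nesting guarantees hold by construction and
are asserted on every run. The q% level is the largest threshold whose
superlevel set holds at least q% of the mass; areas are cell counts × cell
area. Contours are not clipped to water, so areas can overlap land. For an
isotropic Gaussian COA cloud the 50/95% areas agree with the closed-form
ellipse areas of N(0, σ²+h²) within a few percent at n = 20,000 (tested at
10%).

## Gridded HMM geolocation

States are 0.25° cells with a boolean water mask (≥2 water cells required).
The daily transition kernel is an isotropic Gaussian in great-circle
distance, hard-truncated at `2 m/s × 86,400 s = 172.8 km`, with σ chosen so
99% of untruncated 2-D Gaussian mass lies inside the bound
(σ = 172.8 km / √(2 ln 100)); rows are renormalized over water. Daily
likelihoods multiply a Gaussian longitude match (light-based estimate,
default σ = 1°), a Gaussian SST match against the day's field (default
σ = 0.5 °C — the only latitude information, by design, which makes
posteriors anisotropic), and the mask; days with no sensors are uniform over
water; days with a 12-h acoustic COA are clamped to that cell as a delta
likelihood in the *filtered* recursion, which propagates through smoothing.
Forward–backward runs with per-step renormalization and returns the
log-evidence; a zero-mass day raises an error naming the date. The most
probable track is a joint Viterbi path (steps confined to kernel support by
construction) reported with the per-day posterior mode and the 95%
highest-posterior-density cell-set area. Vectorised smoothing agrees with an
explicit per-state loop implementation to 1e-8 on 15×15 grids. The
observation models are simple Gaussian stand-ins for a proprietary
geolocation processor whose internals are not public; this module is a
faithful desk-scale analogue of the described structure, not a clone.

## Synthetic data generator

The generator emulates the study conditions: 19 animals over a two-year
window on a 15-station in-bay array in five regions (the two farthest
stations ~29 km apart, in-region spacing ~2 km) plus offshore stations ~70
and ~125 km south; tag delays i.i.d. uniform(310, 410) s; a logistic
distance-detection curve with p(0) = 0.95, p(540 m) = 0.5, p(1,080 m) = 0.05
and a hard cutoff at 1,100 m representing the reef noise floor (without the
cutoff, the fat logistic tail emits sporadic 1.2–2 km detections that the
singles filter then removes as noise, which would misstate the filters'
false-positive rate on genuine records).

**Presence.** Each animal's daily in-bay state is Bernoulli with
`logit p = −0.3 + 1.6·cos(2π(doy−285)/365) + 1.2·chla + 0.4·moon`, giving
the observed seasonal range of roughly 20–90% presence with a fall peak.
Day-to-day persistence comes from a latent Gaussian AR(1) copula (ρ = 0.85)
thresholded at the daily probability: marginals remain exactly
Bernoulli(p_t) — so the calibration audit is exact — while absences run for
days to weeks as they do in real arrays.

**Movement.** Receivers in such studies sit at aggregation sites, so animals
alternate dwell bouts at stations (30 min floor + exponential extra, tight
150 m jitter under mean reversion) with longer bouts at open-water roam
spots (≥2 km from any station, drawn around the month's seasonal activity
centre), connected by directed 0.2 m/s transits; bay↔offshore commutes after
a presence-state flip run at 1.2 m/s (observed travel rates for this species
reach 50 km/day). Every step displacement is hard-capped at 2 m/s × Δt. The
seasonal centres and preferred station regions shift north in winter, south
in spring, to the channel mouth in summer and to the central reefs in fall,
reproducing the winter-dispersed / fall-concentrated monthly KUD pattern.
This site-visit process replaces a plain mean-reverting walk: a free-running
walk makes receiver-to-receiver implied speeds exceed the 2 m/s filter and
scatters isolated range-edge detections, so the three filters would remove
several percent of genuine records — unlike real bout-structured data, where
the measured genuine loss at default noise settings is ~0.6% with 100% of
injected noise recovered.

**Noise.** Echoes are cross-receiver ghost decodes 1–5 s after a genuine
detection (a same-receiver duplicate would be invisible to all three
filters); false singles are placed on in-bay receivers rejection-sampled to
be ≥2 h from any other detection of the tag, matching their description as
isolated false detections.

**Environment and geosensors.** Moon fraction is a 29.53-day raised cosine
in [0,1]; chlorophyll-a is lognormal around a seasonal cosine with a summer
peak. The geosensor series adds Gaussian noise (σ = 1°) to daily true
longitude and samples a smooth meridional SST field (σ = 0.5 °C) at the true
position; the land mask places coastline along 37.0°E. Four in-bay receivers
drop out one to four months early, providing the varying-effort signal for
the nStations term.

All randomness flows from one `SeedSequence(seed)` through children spawned
in a fixed order; equal seeds give byte-identical outputs end to end
(asserted through the CLI at file level). `simulate_hourly_presence`
additionally draws the animal × hour table directly from a known logit for
model audits, bypassing the detection process.

### What the synthetic tests do not show

The generator has independent daily presence structure given the covariates,
no tides, currents, diel range variability or collision physics, Gaussian
sensor errors, and detection bouts whose durations are chosen for realism
rather than fitted to data. Passing tests therefore demonstrate that the
*pipeline* computes the intended quantities and recovers known structure —
not that real detection data satisfy these models. Reported quantities tied
to the original raw data (deviance explained, mean event duration, absolute
KUD areas) are not reproduction targets for the same reason.

## Problem sizes

Default test/audit sizes are chosen to exercise the statistics at meaningful
scale: QC and residency audits use 6 animals × 6–12 months (~20,000
detections); GAMM truth-recovery uses ~52,000 animal-hours and the AIC
selection study 20 replicates of ~9,600 rows over all 16 candidates; HMM
oracle checks use 15×15 grids; the end-to-end determinism check runs the
full CLI twice on 4 animals × 4 months. The full suite runs in about one
minute.
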