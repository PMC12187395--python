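# Methods

`aeroecho` turns echo-level tables from a vertical-looking biological
radar, plus hourly weather series, into migration traffic rates, circular
direction statistics, seasonal phenology, corridor-wide flux estimates and
boosted-tree models of the meteorological drivers of insect migration.
This note records the models, the defaults that matter, and the design
choices made where more than one convention was defensible.

## Echo filtering

The radar classifier attaches per-class probabilities (percent) to every
detection. The analysis set keeps an echo iff

1. its **cumulative bird probability** — the sum over all bird-class
   probability columns — is ≤ 50% (strictly greater is excluded, so
   exactly 50 is retained);
2. its **wingbeat frequency** is ≥ 10 Hz (insects below 10 Hz are rare and
   overlap vertebrate signatures);
3. its altitude lies strictly between 50 m (ground clutter, local
   foraging) and 500 m (insect detection ceiling) above ground.

Both altitude bounds are exclusive; ties at exactly 50/500 m are removed.
Removals are attributed to the *first* failing rule in the order above.
Which classifier classes count as "bird" is configurable because radar
exports differ; the default sums every `bird_prob_<k>` column.  Missing
displacement direction or ground speed never excludes an echo — the
antenna rotates (and therefore measures direction) only half of the
collection time, and direction-less echoes still represent crossings.

## Diel periods and sun times

Day is the half-open interval [sunrise, sunset); the night that starts at
a given sunset is labelled with that date, so one night spans midnight
under a single label. A timestamp exactly at sunrise belongs to the day.
Sunrise and sunset come from the NOAA solar-position equations (zenith
90.833°, i.e. refraction plus solar radius), iterated so the equation of
time and declination are evaluated at the event itself; accuracy is well
under a minute at mid-latitudes. Latitudes poleward of ±66.5° are
rejected explicitly rather than mishandled.

## Migration traffic rate

A target at altitude h crosses an effective transect of width
w(h) = 2·h·tan(θ/2), with θ the half-power beamwidth (default 25°; both θ
and the width function are configuration hooks because the radar vendor's
internal normalisation is not public). The MTR of a diel period is

    MTR = (1 / f_obs) · Σ_i 1 / w(h_i)   [insects km⁻¹ period⁻¹]

where f_obs is the duty fraction actually observed (default 40/60: the
radar collects 40 min of every hour). Every retained echo contributes,
including direction-less ones; no extra correction is applied for the 50%
antenna-rotation share, which affects only direction availability. MTR is
exactly linear in echo count and inversely proportional to the duty
fraction. Absolute MTR values are convention-dependent (they scale with
1/θ); ratios, percent contrasts and the extrapolation arithmetic are not.

## Circular statistics

Angles are geographic: degrees clockwise from north, so the north–south
component of a sample is its mean cosine. For a sample of n angles,
C = Σcos, S = Σsin, r = √(C²+S²)/n, and the mean direction is
atan2(S, C) mapped to [0, 360). r = 0 flags the mean as undefined rather
than silently reporting 0°. The Rayleigh statistic is z = n·r² with the
standard small-sample-corrected exponential p-value, clipped to (0, 1].
Two dispersion measures are reported because the field uses both: the
angular deviation √(2(1−r)) and the circular SD √(−2 ln r).

Watson's two-sample U² uses the rank formulation on the pooled circular
ordering and takes its significance from label permutations
(p = (1 + #{U²* ≥ U²}) / (B + 1)), valid at any sample size; heavy ties
(> 50% duplicates) are broken by an O(10⁻⁹ degree) jitter drawn from the
recorded seed. The statistic is invariant to a joint rotation of both
samples.

Seasonal mean directions are **second-order**: the circular mean of
per-period mean directions, so each day or night weighs equally
regardless of its echo count. Per-period summaries use only echoes with a
measured direction and are flagged insufficient below 10 directional
echoes (configurable) and significant when the Rayleigh p < 0.05.

Downwind direction is atan2(u, v) on the eastward (u) and northward (v)
wind components — the compass direction the air moves *toward*; calm air
is flagged undefined.

## Seasons, flux and biomass

Season windows (inclusive) are: spring 1 Mar–10 Jun (102 days), summer
11 Jun–31 Jul (51), autumn 1 Aug–30 Nov (122), winter 1 Dec–29 Feb
(90/91). They partition every calendar year; 29 Feb is winter. The
extrapolation

    total = (mean day MTR + mean night MTR) · width_km · n_days
    biomass_kg = total · mean_mass_mg · 10⁻⁶

uses the calendar window lengths (the only lengths consistent with the
published corridor totals), a default corridor width of 70 km and a mean
individual mass of 50 mg for radar-detectable (>10 mg) insects — a
literature value from UK aerial sampling, not locally validated, so
biomass is indicative. Seasonal means pool period records across sites
unweighted; the 10th/90th percentiles use linear interpolation. Biomass
is reported unrounded in kg (tonne rounding is presentation-level only);
the autumn figure computes to 16.6 t under these assumptions.

Mass-migration events have no standard quantitative definition, so the
detector is deliberately scale-free: a period is an event iff its MTR
exceeds the stratum's 90th percentile *and* exceeds twice the median of
the surrounding 7-period window (self excluded). All three parameters are
exposed.

## Weather coupling and boosted regression trees

Hourly weather is averaged into each diel period by hour-start timestamp
(half-open window, same convention as echo assignment); periods with no
matched hours are flagged and excluded. The model matrix per stratum
(season × phase; spring/autumn × day/night gives the four standard
strata) has response log(MTR + 1) and predictors: temperature, u and v
wind, humidity, cloud cover, vorticity, vertical motion, numeric
day-of-year, and site as a categorical. Pairwise predictor correlations
are reported before fitting, flagging |r| > 0.7.

The boosting engine is stagewise least squares: at each step a
best-first, depth-limited regression tree is fitted to the current
residuals on a bag-fraction subsample and added with shrinkage.
Defaults follow ecological practice: learning rate 0.01, tree complexity
12 (maximum splits per tree, i.e. interaction order), bag fraction 0.75,
10 folds, steps of 25 trees, Gaussian loss, minimum 10 observations per
leaf. Categorical predictors split on level subsets found by ordering
levels by mean response (optimal for squared error). Ensemble size is
chosen by stepwise cross-validation: fold assignment is fixed up front
from the run seed, each step adds 25 trees to every fold model, and
growth stops after 5 steps (configurable patience) without improvement in
pooled out-of-fold squared error, or at a 10,000-tree cap with a warning.
The reported `cv_correlation` is the Pearson correlation between
out-of-fold predictions at the selected size and the response.

Relative influence credits each split's squared-error improvement to its
split variable, summed over the selected trees and normalised to 100.
Partial dependence pins one predictor to a grid and averages the model
prediction over the training rows. All stochastic elements (bagging, fold
assignment) flow from the config seed; refitting with the same seed is
bit-identical.

Exact invariances worth knowing: the training-deviance path is
non-increasing in practice at small learning rates but is not a
mathematical guarantee under bagging (each tree is fitted on a subsample,
scored on all rows); with bag fraction 1 and a non-binding leaf-size
floor, fits are exactly invariant to duplicating every row.

## The synthetic campaign generator

No public echo-level dataset accompanies the analysis, so the generator
plants a known truth with the statistical structure the estimators
assume. Every distributional choice is a stand-in (the truth record says
so) — passing recovery tests demonstrates estimator correctness under
this model, not fidelity of the model to any particular field campaign.

Per site and diel period:

* **Counts.** The true number of insects crossing a 1-km reference
  transect is negative-binomial (gamma–Poisson, dispersion k = 1.5 by
  default) with log-mean = log(base rate × season multiplier) + planted
  weather coefficients × period-mean weather anomalies. Day-to-day
  variation in real traffic rates is large, hence negative-binomial
  rather than Poisson. Season multipliers default to spring 1.25, autumn
  1.0, summer 0.3, winter 0.2 (two migration peaks, quiet summer/winter).
  Default base rates (290 echoes/day period, 170/night at zero anomaly)
  are set so the implied true daytime flux sits ~14% below the nightly
  flux once beam thinning is accounted for.
* **Detection.** Each true crossing at altitude h is detected with
  probability duty · w(h)/W_ref (W_ref = 1 km), so the MTR estimator has
  a known flux to recover and detection is genuinely altitude-biased.
* **Altitudes.** Day: normal, centred 300 m (sd 80), truncated to
  (50, 500) — modal band 280–320 m. Night: exponential decay from the
  50 m floor (scale 110 m), truncated at 500 m — maximum below 150 m,
  monotonically decreasing above.
* **Directions.** Von Mises around the planted seasonal mean (spring
  day 2°, night 338°; autumn day 205°, night 192°; κ = 2), weakly
  concentrated off-season (κ = 0.2). Half the echoes (the rotating-antenna
  share) carry a measured direction.
* **Wingbeat and speed.** Daytime WBF is a two-mode normal mixture at 15
  and 30 Hz (sd 3); nocturnal WBF is confined to 25–50 Hz. Ground speeds
  are normal, 5.6 ± 0.9 m s⁻¹, shifted +0.4 at night and +0.3 in spring.
* **Contaminants.** A configurable fraction (default 1.6%) of rows are
  bird-like: cumulative bird probability in 55–95%, half of them also
  with WBF < 10 Hz, so both classification filters are exercised.
* **Weather.** Hourly series with AR(1) anomalies around a seasonal +
  diurnal temperature climatology; mean wind (u = 2.3, v = −1.3 m s⁻¹)
  blows toward ~120° (east/southeast). Planted count effects: positive
  temperature everywhere in the migration seasons, positive southerly
  (tailwind) component in spring, negative northerly and eastward
  components in autumn, negative daytime humidity.

All randomness flows from a single seed through per-site, per-purpose
substreams (`SeedSequence` spawn keys), so identical configs reproduce
bit-identical tables.

What the generator does **not** emulate: spatial correlation between
sites beyond the shared climatology, radar sensitivity drift, target-size
(RCS) dependence of detection, within-period autocorrelation of arrivals,
and real weather–topography interactions. Results on synthetic data bound
estimator behaviour, not ecological effect sizes.

## Problem sizes used in the shipped checks

The default validation campaigns are deliberately modest so the whole
suite runs quickly on one core: ~25-day single-site campaigns (≈50 diel
periods, 200–400 echoes per period) for estimator recovery, a one-year
single-site campaign (≈90k echoes) for the end-to-end phenology, 2,000
replicates for the Rayleigh type-I rate, 10,000 for analytic-vs-null
p-value agreement, 199–999 permutations for Watson U², and boosted-tree
designs of 250–500 rows. These sizes were chosen as the smallest at which
the quantities of interest are statistically stable.

## Known limitations

* Absolute MTR depends on the assumed beamwidth; only relative quantities
  transfer across conventions.
* The Rayleigh p-value is asymptotic-with-correction; below n = 3 it is
  refused rather than approximated.
* The stepwise CV stopping rule (patience on pooled out-of-fold error) is
  one of several plausible readings of the classic `gbm.step` behaviour;
  cap, patience and folds are all configurable.
* `tree_complexity` is interpreted as the maximum number of splits per
  (best-first) tree; a fixed-depth reading would give slightly different
  ensembles and can be emulated by adjusting the knob.
* Biomass conversion assumes a single 50 mg mean mass for all
  radar-detectable insects.
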