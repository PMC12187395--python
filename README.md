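# aeroecho

Radar-aeroecology analysis of large-insect migration through a narrow
coastal corridor: from echo-level vertical-looking-radar detections and
hourly weather fields to filtered insect tables, day/night **migration
traffic rates (MTR)**, circular direction statistics, seasonal phenology,
corridor-wide flux and biomass estimates, and boosted-regression-tree
models of the meteorological drivers of migration intensity.

The package is written for aeroecologists working with BirdScan-style
vertical-beam radar exports (one CSV row per detected target with
altitude, wingbeat frequency, displacement direction, ground speed and
per-class classification probabilities) coupled to ERA5-style hourly
weather (wind components at flight altitude, temperature, humidity,
cloud, vorticity, vertical motion). Because no public echo-level dataset
exists for this system, `aeroecho` ships a first-class synthetic campaign
generator that plants a known ground truth — per-period flux, seasonal
direction reversal, altitude profiles, weather effects — so every
estimator in the pipeline can be validated against it.

## The statistics at the core

**Migration traffic rate.** A target at altitude *h* crosses an effective
transect of width *w(h) = 2·h·tan(θ/2)* (θ the half-power beamwidth).
For one diel period (sunrise→sunset day, sunset→sunrise night, sun times
from the NOAA solar equations):

    MTR = (1 / f_obs) · Σᵢ 1 / w(hᵢ)      [insects km⁻¹ period⁻¹]

with *f_obs* the observed duty fraction (default 40/60). Corridor-wide
seasonal flux is `(mean day MTR + mean night MTR) × width_km × n_days`,
and biomass applies a 50 mg mean mass.

**Circular statistics.** Geographic angles (0° = north, clockwise); mean
resultant length *r*, Rayleigh test *z = n·r²* with the small-sample
corrected p-value, north–south component = mean cosine, and Watson's
two-sample *U²* with permutation significance for comparing insect
displacement against the downwind direction atan2(u, v).

**Boosted regression trees.** Stagewise least-squares boosting (learning
rate 0.01, tree complexity 12, bag fraction 0.75, Gaussian loss) on
log(MTR + 1) per season × phase stratum, with ensemble size selected by
stepwise 10-fold cross-validation in 25-tree increments; outputs relative
influence (sums to 100) and partial-dependence curves.

## Worked example

Simulate a one-year single-site campaign and run the full pipeline:

```python
import datetime as dt
from aeroecho import RunConfig, run_pipeline
from aeroecho.synthetic_radar import SimulationConfig, SiteMetadata

sites = [SiteMetadata("hula", 33.1, 35.6, 70.0,
                      dt.date(2021, 1, 1), dt.date(2021, 12, 31))]
run_pipeline(RunConfig(output_dir="run/",
                       sim_config=SimulationConfig(seed=5, sites=sites)))
```

which logs, stage by stage,

```
input: 92239 echoes, 8784 weather hours
filter: 92239 -> 90754 rows
mtr: 732 diel periods
```

and writes `filtered.csv`, `mtr.csv`, `directions.csv`,
`seasonal_directions.json`, `flux.json` and a reproducibility manifest.
On this campaign the seasonal summaries read (from
`seasonal_directions.json` and `flux.json`):

| stratum      | mean direction | r     | Watson U² vs downwind |
|--------------|----------------|-------|-----------------------|
| spring night | 337.7°         | 0.996 | p = 0.001             |
| autumn night | 191.5°         | 0.991 | p = 0.001             |

i.e. the planted migratory axis — northwards in spring, southwards in
autumn — is recovered, and insect displacement differs significantly from
the prevailing east/southeast-ward downwind direction, the signature of
active seasonal navigation. Spring mean nightly MTR exceeds autumn
(4808 vs 3775 insects km⁻¹ night⁻¹ here), mirroring the stronger spring
passage.

The same stages are available from the shell:

```sh
aeroecho simulate --seed 5 --out run/
aeroecho filter --in run/echoes.csv --out run/filtered.csv --report run/report.json
aeroecho mtr --in run/filtered.csv --sites run/sites.csv --beam-deg 25 --out run/mtr.csv
aeroecho flux --mtr run/mtr.csv --width-km 70 --mass-mg 50 --out run/flux.json
aeroecho brt --mtr run/mtr.csv --weather run/weather.csv --sites run/sites.csv \
         --stratum spring:night --out run/brt.json
```

Feeding the seasonal mean traffic rates of the studied corridor
(day 24,393 / night 28,393 insects km⁻¹ in spring; 18,969 / 19,923 in
autumn) through `extrapolate_flux` with the 70 km corridor width and the
calendar season windows gives 376.9 million insects per season in spring
(≈19 t at 50 mg each) and 332.1 million in autumn (16.6 t) — 88% of the
spring passage, and over 700 million radar-detectable insects per year.

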