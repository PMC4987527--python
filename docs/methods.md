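# Methods

## The prevalence model

The package estimates the number of people living with ALS in a region and
year as a band-wise stationary approximation: expected cases in stratum
(sex `s`, age band `a`) are `I(s,a)/100,000 × N(s,a,t) × D`, with `I` the
incidence rate per 100,000 person-years, `N` the stratum population and `D`
the region's median disease duration in years. The approximation assumes

- incidence constant over calendar time (empirically reasonable for ALS,
  and the reason the same schedule is applied to both projection years);
- duration short relative to band width, so cases are counted in the band
  where they arise (within-duration ageing across band boundaries is
  ignored);
- a stationary onset process, so point prevalence equals incidence ×
  duration.

The model deliberately multiplies by the **median** duration, the summary
reported by ALS survival studies. For a skewed duration distribution the
stationary prevalence actually scales with the **mean**; with exponential
durations the mean exceeds the median by the factor `1/ln 2 ≈ 1.44`. The
microsimulation (below) exists to quantify this kind of gap, not to
correct it: the projection's output is defined as the median-based product.

No uncertainty intervals are produced; the inputs carry no sampling
variances, and case counts are reported as real-valued expectations.

## Age axis and harmonization

Age bands are closed integer-year intervals; a "5-year band" 15–19 has
width 5, and open-ended bands (75+, 100+) carry an explicit flag rather
than a sentinel age. Population pyramids must cover exactly the 21-band
grid 0–4 … 95–99, 100+ per sex; missing bands are an error, never imputed.

Study incidence bands rarely match that grid. `harmonize` assigns each
grid band the study rate weighted by the fraction of the grid band's whole
years that the study band covers, assuming a uniform age distribution
within bands (band 18–24 contributes 2/5 of its rate to grid band 15–19).
This conserves expected case mass whenever study bands are unions of grid
bands, keeps every effective rate within [0, max study rate], and is
idempotent on already-aligned schedules. Two documented switches alter the
defaults for sensitivity analyses: `overlap="full"` carries the whole rate
into partially covered bands, and `extend_oldest=True` propagates a bounded
terminal band's rate into older bands (elderly ALS incidence is plausibly
under-ascertained, so the default of 0 above the oldest study band is
conservative). Ages below the youngest study band always get rate 0:
juvenile ALS is out of model.

## Pooling and extrapolation

Where a continent is represented by several studies, pooled band rates and
the pooled duration are convex combinations with weights proportional to
each study's catchment population (weights normalised to sum to 1; scaling
all catchments leaves the pool unchanged). Catchment population — not
person-years of observation — is used as the weight, since person-years
are rarely reported. Continents with one source study reuse that study's
schedule relabelled. The continent→source assignment and pooling
membership are plain CSVs, so alternative assignments (e.g. where to place
Central America, or whether a small national study joins a continental
pool) are one edit away rather than code changes.

## Synthetic worlds

`generate_world` emulates the statistical structure of the real inputs
under a single integer seed:

- **Pyramids**: a discretised exponential age density over single years
  0–104 with region-specific scale drawn in [30, 40] years; the second
  epoch multiplies the scale by (1 + ageing index, default 0.2) and the
  total by a growth factor (default 1.15), shifting mass into the 60+
  bands. Sex split is drawn near 0.5.
- **Incidence**: 10-year study bands from age 20 plus an open 80+ tail,
  plateauing over 60–79 at a peak rate (default 6 per 100,000, the order
  observed in European populations), decaying multiplicatively per decade
  younger (default 0.45) and dropping in the open tail (default 0.6), with
  a male excess factor (default 1.3) and mild lognormal region jitter.
- **Durations**: uniform in 2–4 years, the range of reported ALS median
  survival. **Catchments**: uniform in 0.5–5 million.

Alongside the data the generator returns closed-form expected case counts
computed by direct loops over study bands (every study band is a union of
grid bands, so coverage is exact containment) — deliberately independent
of `harmonize`/`project_cases`, so recovery tests compare two separate
arithmetic routes. What the synthetic world does **not** emulate: realistic
pyramid shapes beyond a monotone exponential (its median ages, ~21–28 y,
are younger than the studied countries'), migration or cohort structure,
diagnostic-criteria differences between studies, or any calibration of
rates to specific countries. Passing recovery tests therefore demonstrates
the pipeline's arithmetic and plumbing, not the realism of any particular
national estimate.

## Microsimulation oracle

`microsim_prevalence` simulates an illness–death process per grid band:
onsets follow a Poisson process with intensity rate/100,000 × band
population per year over a stationary window, each case draws a duration —
fixed at the median by default, or exponential with that median
(scale = median/ln 2) — and prevalent cases are counted at a census
instant. The window is the duration itself for fixed durations and 40/ln 2
medians for exponential ones (survival beyond that is negligible). The
mean over replicates should bracket the closed-form product within a few
Monte Carlo standard errors; tests and the acceptance script use 200
replicates and a 3-SE band over five seeded scenarios, which runs in
seconds on one CPU.

## Numerical and reporting conventions

- All computation is unrounded; rounding — half away from zero, matching
  how the reference table is printed — happens only in report formatting.
  (Summing the printed ten-region table's rounded cells misses the printed
  sex totals by one case in each column, a pure display artefact the
  unrounded engine does not inherit.)
- Median population age interpolates linearly within the band containing
  the 50th percentile, treating the open 100+ band as 5 years wide; exact
  boundary ties resolve to the earlier band's upper edge.
- Shares within an aggregation sum to 1 to 1e-9; pooling weights to 1e-12.
- CSV readers use round-trip float parsing so write→read is the identity
  on schedules, durations and pyramids.
- Percent changes in human-readable reports are presented as integers;
  machine-readable JSON carries both the unrounded and rounded values.

## Design choices where the design was open

- Combined-sex incidence rows are rejected rather than split: the
  projection is sex-specific throughout and any split rule would invent
  information.
- The MND-vs-ALS case definition is carried as metadata and surfaced in
  reports but never used to rescale rates; the known overestimate from
  motor neuron disease definitions is a caveat, not a correction.
- Populations under age 20 enter the pyramid but contribute zero cases
  through absent rates, rather than being excluded from the input — the
  two conventions are numerically identical when the youngest study band
  starts at 20.
- The published reference table ships as in-package data for the
  aggregation-only analytics; per-study incidence rates and durations do
  not (they are supplementary material, user-supplied at run time), so
  repository fixtures for the full pipeline are always synthetic and
  labelled as such.

## Known limitations

- No demographic modelling of our own: population futures are inputs, and
  their vintage matters (reports print the recorded vintage; current
  database vintages differ from older ones).
- Improving survival over time, elderly under-ascertainment and
  study-methodology heterogeneity are documented sources of bias that the
  model does not correct; they bias the projection downward.
- The global extrapolation inherits whatever unrepresentativeness the
  source studies have for their continents, most severely where a single
  small study stands for a large continent.
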