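# Methods

`pmbpop` models releases of a paternal-male-bias (PMB) transgenic strain of
*Anopheles gambiae* — an autosomal construct whose carrier males sire ~95%
male progeny because an I-PpoI nuclease shreds the X-bearing sperm's rDNA
target — into wild-type populations at two scales: replicated 16 m³ insectary
cage trials, and a single West-African village population. This note
documents the models, their parameters, the numerical choices, and the
limits of what the synthetic-data tests demonstrate.

## Shared demographic core

Both models are daily-step stochastic simulations over the same classes:
juveniles (by age, genotype, sex), unmated adult females (by genotype),
adult males (by age and genotype), and mated adult females (by own and mate
genotype). Shared rules:

- **Development.** Juveniles emerge as adults 10 days after oviposition.
- **Mating.** A newly emerged female mates once, with a male drawn uniformly
  at random among all living males, on the day of her emergence (males of
  all genotypes and ages are equally competitive; life-table and
  mating-competition experiments found no transgene fitness costs and 54%
  mating success against wild males, consistent with equality). Her mate's
  genotype is recorded permanently. If no males are alive she remains
  unmated and retries daily.
- **Fecundity.** Each mated female lays a Poisson(9) number of viable eggs
  per permitted day, from the day after mating (the experimental blood-meal
  cadence implies at least a short lag; demographically this one-day lag is
  minor against a multi-week cage lifespan or an 8-day expected village
  lifespan).
- **Inheritance.** Egg genotypes are multinomial with exact single-locus
  Mendelian probabilities for the autosomal construct (each parent transmits
  0 or 1 copies; quarters are exact binary fractions). Egg sexes are
  independent Bernoulli draws with male probability 0.95 when the father is
  hemi- or homozygous, 0.5 otherwise; the mother's genotype never distorts
  the sex ratio. Genotype and sex are drawn independently — the only
  consistent joint law for an autosomal construct acting through sperm.
  The bias is a parameter (`male_bias`, default 0.95).

A population with no transgenic individuals and no releases is an absorbing
state: the transgene can never arise de novo.

## Cage model

The simulated week is anchored with day 0 a Monday. Oviposition occurs only
on Mondays and Thursdays; all adult additions (establishment, restocking,
releases) occur on Tuesdays and Fridays, matching the twice-weekly
experimental cadence.

- **Restocking.** On each oviposition day a random sample of 100 eggs
  (multivariate hypergeometric across genotype-by-sex classes) is kept, all
  of which survive to emerge 10 days later; restocked-sample composition is
  the trial observable (proportion female, transgene frequency). Juvenile
  mortality is deliberately absent from the cage model even though the
  life-table studies measured 8.5% larval and 6.6% pupal mortality — the
  restocking design fixes recruitment at the sample size, so juvenile
  survival would only rescale an egg pool that is already far larger than
  the sample.
- **Adult survival** is age-dependent: a Weibull lifespan is drawn at
  recruitment and the adult is removed on the first day its age exceeds it.
  Defaults use shape 4.0 for both sexes with scales set so the medians match
  the survival experiments (males 28 d, females 30 d). The shape is not
  identified by the reported medians alone; 4.0 leaves ~3% of males and ~7%
  of females alive at the 42-day censor point, consistent with the
  experiment's "almost all dead" endpoint, and is configurable.
- **Protocols.** Trials 2–3: 50 females + 50 males twice weekly for 4 weeks,
  then twice-weekly releases of 0 (control), 50 (1:1) or 150 (3:1) zero-age
  hemizygous males for 4 months. Trial 1: a day-0 draw of 300 females + 178
  males from a stable-age population, 60+60 twice weekly for 3 weeks, 50+50
  for 3 weeks, then 2 months of releases from day 42. "Months" are
  implemented as 30 days of releases after the first release day
  (configurable); the trial-1 stable draw assigns stationary-age residual
  lifetimes (age density ∝ S(a); residual lifetime from the conditional
  Weibull law) and mates all initial females to wild-type males.
- **Step order** within a day: deaths → emergences (new females mate) →
  scheduled additions and releases (added virgin females also mate that
  day) → oviposition and restock sampling → census.

### Mean-field equilibrium oracle

With O offspring recruited per week (200 under the default restocking), R
males released per week, equal male lifespans, and transgenic mothers,
homozygotes and age structure neglected, the equilibrium transgenic
fraction p of the male pool solves

    0.45·O·p² + (0.025·O + R)·p − R = 0,

giving offspring female fraction F = 0.5 − 0.45·p and offspring transgene
frequency q = p/2. For the 1:1 and 3:1 protocols (R = 100, 300):
p ≈ 0.621, 0.796; F ≈ 0.220, 0.142; q ≈ 0.311, 0.398. This deterministic
approximation is used purely as a test oracle.

**Known limitation — the post-day-45 window carries a transient.** The
summary window opens ~17 days after releases begin, while the simulated
system relaxes to equilibrium through two successive ~28–30-day turnover
stages (first the male pool, then the mated-female pool whose mates were
chosen earlier). Ensemble means over the final month of the 1:1 and 3:1
trials sit on the oracle (F ≈ 0.235 and 0.141), but the full post-45 means
are higher for females (≈ 0.287 and 0.192) and lower for transgene
frequency (≈ 0.251 and 0.367). An independent deterministic expected-value
replica of the model reproduces the same window means, so this is a
property of the model and window, not of the stochastic implementation; the
acceptance suite records the discrepancy rather than widening the bands.

## Village model

The village model replaces restocking with natural recruitment and
rainfall-driven density dependence, and replaces age-dependent adult
survival with constant daily probabilities (mortality outdoors is dominated
by age-independent hazards): males 0.77/day by default (0.69–0.87 bracket
from mark-release-recapture), females 0.875/day.

- **Juvenile mortality.** Each day every juvenile survives with probability
  (1 − 0.05) × (α(t)/(α(t) + J_T))^(1/10), where J_T is the start-of-day
  juvenile total (synchronous update). The 0.05 is density-independent
  background mortality; the second factor composes over the 10-day
  development to a cumulative competition survival of α/(α + J_T), so α(t)
  is the juvenile count at which the probability of death from competition
  over development is one half. (Read as a daily survival: the printed form
  equals 1 at J_T = 0 and only composes to the stated half at J_T = α under
  this reading.)
- **Carrying-capacity driver.** The exact dependence of α(t) on rainfall
  and water courses is not reproducible here, so a pluggable driver
  provides the default α(t) = c·(L + r·m₁₄(t)), with L = 2 km of water
  courses (a permanent dry-season floor), r = 0.5 per mm, and m₁₄ the
  trailing 14-day mean of the (weekly, repeated to daily) rainfall series.
  The constants were chosen for a Sahelian-like ~10× wet:dry seasonal
  fluctuation; the global scale c carries the units and is never set by
  hand — `calibrate_alpha` bisects on log c until the mean unperturbed
  adult-female count at the end of the rainy season (day-of-year 304, Oct
  31) of the release year matches a target (35,500 by default) within 5%,
  using the same replicate seeds at every iteration so the search sees a
  monotone objective.
- **Simulation design.** Two years of burn-in from an arbitrary all-wild-type
  start (1,000 mated females, 1,000 males, proportional juveniles) erase the
  initial conditions; hemizygous males are released on a schedule in year 3.
  `make_schedule` builds weekly/fortnightly/monthly/quarterly schedules with
  identical cumulative totals (remainder to the final event). Step order:
  juvenile thinning → emergence and mating → adult survival → releases →
  oviposition → merge newly mated females (they lay from the next day).
  Adult male age is demographically inert under constant survival and is
  not tracked.

**Known limitation — substitute seasonality and suppression strength.**
With the default driver the calibrated village collapses to ~6–8 thousand
females in the dry season. Weekly releases then dominate the male pool
before the rains (a transgenic male fraction near 0.6 at 5,000/week and
above 0.9 at 50,000/week), so the transgene enters the wet season at high
frequency and end-of-rainy-season suppression comes out stronger (~35% at
5,000/week; ~7–9 thousand females left at 50,000/week) than the source
model this package emulates (~25% and ~13,500), whose carrying-capacity
profile evidently has a shallower seasonal trough. The discrepancy scales
with release size and also explains why a single large quarterly pulse is
not quite equivalent to weekly releases at equal totals here (weekly,
fortnightly and monthly schedules agree within ~3% of the unperturbed
count; the quarterly arm differs by up to ~17%). The acceptance suite
reports these numbers as computed.

## Synthetic data

The generators supply every input without downloads, each deterministic
under a fixed seed and labelled with its distributional assumptions:

- **Rainfall** — weekly depths from a wrapped-Gaussian seasonal bump
  (peak day-of-year 213 ≈ Aug 1, 60 mm/week at peak, 1 mm/week dry floor,
  width 60 d) with unit-mean multiplicative lognormal noise (CV 0.3). It
  emulates a Burkina Faso-like unimodal monsoon; it has no dry spells,
  storm clustering or interannual trend, so village results say nothing
  about drought years or bimodal regimes.
- **Survival experiment** — 12 cages × 30 adults per sex, daily death
  counts right-censored at 42 d, from per-sex Weibull draws. Closing the
  loop, the censored Weibull fitter recovers the generating medians within
  ±1.5 d at this design size.
- **Observation noise** — binomial screens at the experimental sample sizes
  (~200-egg hatch samples, 100-individual restock screens), unbiased by
  construction, with an optional beta-binomial overdispersion hook for
  field-style data.

Passing tests on these generators demonstrate internal consistency of the
models and estimators, not fidelity to any particular field season.

## Fitting and summaries

- **Censored Weibull MLE.** Daily counts make lifespans interval-censored:
  a death on day d contributes S(d−1) − S(d); survivors at the censor day
  contribute S(42). The likelihood is maximised over (log shape, log scale)
  with Nelder–Mead from a moment-style start; zero events or a single death
  day raise errors (the shape is unidentifiable). The implementation is
  cross-checked in the tests against an independent interval-censored
  Weibull fitter.
- **Ensembles.** Replicate runs use consecutive seeds (base..base+n−1) of
  independent PCG64 generators. The "95% CI" band is the pointwise
  empirical 2.5–97.5 percentile envelope over replicates (order statistics,
  hence monotone under monotone transforms); post-day-45 summaries reduce
  each replicate to its mean over collection days after day 45 and report
  the across-replicate mean ± SE. Collection days with no eggs yield NaN
  observables and are excluded from summaries.
- **Problem sizes.** Default analysis sizes are 100 cage replicates per
  treatment and 5 village replicates per release scenario (matching the
  ensemble sizes the envelopes are defined over), with 2–3 replicates for
  auxiliary ordering checks; a full acceptance evaluation completes in
  about a minute on one core.
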