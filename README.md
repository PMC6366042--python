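# pmbpop

Stochastic population models for releases of a **paternal-male-bias (PMB)**
transgenic strain of *Anopheles gambiae* — a strain whose carrier males sire
~95% male progeny — into wild-type target populations.

The package is aimed at vector-control modellers evaluating sex-ratio
distorter strains: it simulates the dynamics of the transgene and the
resulting female suppression in replicated large-cage trials and in a
seasonal West-African village population, parameterizes adult survival from
censored life-table data, and summarises replicate ensembles the way such
trials are compared with model predictions.

## Models

Both simulators share one demographic core. Juveniles emerge 10 days after
oviposition; a female mates once, with a uniformly random male, on the day
she emerges; mated females lay Poisson(9) viable eggs per permitted day; egg
genotypes are Mendelian (multinomial) for the autosomal transgene and sexes
are Bernoulli with male probability

    P(male) = 0.95  if the father is hemi- or homozygous,
              0.5   otherwise.

**Cage model** — Mondays/Thursdays oviposition, 100-egg restock samples
(which all survive), Tuesdays/Fridays adult additions and releases of 0, 50
or 150 zero-age hemizygous males, per-sex Weibull adult lifespans (default
shape 4, medians 28 d male / 30 d female).

**Village model** — natural recruitment with daily juvenile survival

    (1 − 0.05) · ( α(t) / (α(t) + J_T) )^(1/10),

where J_T is the juvenile total and the carrying capacity α(t) follows a
rainfall-driven driver α(t) = c·(L + r·m₁₄(t)) calibrated so the unperturbed
end-of-rainy-season adult-female count matches a stated baseline (35,500 by
default); constant adult daily survival (males 0.77, females 0.875); 2-year
burn-in, releases in year 3.

## Worked example

```python
from pmbpop import build_protocol, cage_ensemble, post45_summary, mean_field_equilibrium

protocol = build_protocol("trial23", "1:1")          # 50 males twice weekly
ensemble = cage_ensemble(protocol, n=100, base_seed=0)
print(post45_summary(ensemble).round(4))
print(mean_field_equilibrium(weekly_offspring=200, weekly_release=100))
```

prints

```
                  mean      se      n
prop_female     0.2870  0.0012  100.0
transgene_freq  0.2514  0.0018  100.0
MeanFieldEquilibrium(p=0.6214026912334133, female_fraction=0.22036878894496403, transgene_frequency=0.31070134561670665)
```

Over the collection days after day 45 of a 1:1 release trial, the model
predicts offspring samples that are 28.7% female (an unperturbed population
is 50% female) and 25.1% transgenic, with the deterministic equilibrium
approximation at 22.0% female / 31.1% transgenic — the gap is the
relaxation transient still inside the summary window (ensemble means over
the final month sit on the equilibrium values).

The same objects exist for the village:

```python
from pmbpop import gen_rainfall, VillageConfig, calibrate_alpha, run_village, ReleaseSchedule

rain = gen_rainfall(years=3, seed=1)
config = VillageConfig()
config.driver = calibrate_alpha(config, rain, target_females=35_500, seed=1).driver
weekly = ReleaseSchedule.regular(5_000, "weekly", start_day=731)
series = run_village(config, rain, schedule=weekly, seed=1)
```

A command-line interface mirrors these flows:

```bash
pmbpop simulate-cage --trial 23 --treatment 3:1 --seed 0 --replicates 100 --out out/
pmbpop calibrate-village --target 35500 --seed 0 --out out/
pmbpop simulate-village --synthetic-rain --release-size 5000 --interval weekly --calibrate --seed 0 --out out/
pmbpop generate survival --out survival.csv && pmbpop fit-survival survival.csv --out out/
```

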