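# distdecay

Distance-decay biogeography of activated-sludge bioreactor microbiomes.

Municipal wastewater treatment depends on the microbial communities of
activated-sludge bioreactors. A central question of microbial biogeography is
whether such communities are randomly assembled or spatially structured — and,
if the latter, whether the structure reflects **environmental heterogeneity**
(nearby facilities receive similar wastewater) or **dispersal limitation**
(microbes simply do not get everywhere). `distdecay` packages the complete
statistical toolkit for answering this from a regional survey: a taxon-count
table, sample/facility metadata and a phylogeny in; decay slopes, driver
attributions and seasonal classifications out. It is written for microbial
ecologists and environmental engineers analysing multi-facility 16S surveys.

## The statistics at the core

The central quantity is the **spatial community shift rate β**, the slope of
the power-law distance decay of community similarity

```
log10(DS) = β · log10(D) + c
```

where `DS` is the community dissimilarity between two facilities (Sørensen,
Bray-Curtis, or weighted UniFrac; bioreactor pairs averaged within the same
collection month) and `D` their great-circle distance in km. Its island-biogeography
analog is the **taxon-volume exponent z**, from `log10(R) = z · log10(V) + c`
with `R` the observed richness and `V` the facility flow rate. Both are fit by
ordinary least squares on the log scale, with linearity summarised by
Pearson's ρ and a two-sided t-test.

Around the regression sit the supporting analyses:

* **Occupancy subgroups** — *universal colonizers* (detected in every sample),
  *ubiquitous phylotypes* (detected at least once in every facility), and the
  *Archaea*; organisms present everywhere are, by construction, not
  dispersal-limited, so their decay slope isolates environmental selection.
* **Mantel tests** (Spearman, permutation p) of dissimilarity against
  geographic distance and environmental difference matrices.
* **Partial-CCA variation partitioning** of the chi-square community inertia
  into pure-spatial, pure-environmental, shared and unexplained fractions.
* **AMOVA** on distance matrices (facility vs parallel-bioreactor structure).
* **Seasonal classification** of each bioreactor from dissimilarity vs
  time-interval regressions: a significant concave quadratic peaking at 5–8
  months marks a cyclic (seasonally returning) community; a significant
  linear fit marks directional drift.

A synthetic-study generator (`distdecay.synth`) emulates a 20-facility /
25-bioreactor / 12-month survey with a planted β, a spatially autocorrelated
environmental driver (influent TKN), and seasonal cycles in designated
bioreactors, so every stage of the pipeline is testable end to end without
any sequencing data.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
(seed 1 shown; all tables land under `results/`):

```
$ python analysis/01_simulate_study.py
study written to results/study
  300 samples, 300 phylotypes, 20 facilities, 25 bioreactors
  facility distances 13-443 km; planted beta = 0.12

$ python analysis/03_distance_decay.py
          sorensen: beta = 0.092 (rho = 0.32, P = 8.2e-06)
       bray_curtis: beta = 0.121 (rho = 0.41, P = 5.3e-09)
         universal: beta = 0.123 (rho = 0.39, P = 2e-08)
        ubiquitous: beta = 0.121 (rho = 0.40, P = 7.4e-09)
monthly decay: median beta 0.127; significant in 12/12 months

$ python analysis/04_drivers_varpart.py
Mantel battery (top 5 by rho_s):
                    TKN_in: rho_s = 0.74* (P = 0.001)
variation partitioning (20 facilities, env = TKN_in, TKN_out, NH3_out):
  pure geographic  20.7% (P = 0.001)
  pure environment 35.7% (P = 0.001)
AMOVA facilities: F = 34.1, P = 0.001 (<= alpha = 0.001)
AMOVA parallel bioreactors of C: F = 0.34, P = 0.878 (not distinguishable)

$ python analysis/05_seasonal_dynamics.py
seasonal (cyclic or both): 15 of 25 -> A1, C1, C2, ...
matches the planted seasonal set: True
```

Reading the output: the planted decay slope 0.12 is recovered (β̂ = 0.121 for
Bray-Curtis, significant at the study-wide α = 0.001); the planted driver
(influent TKN) tops the Mantel battery; environment explains more pure
variance (35.7%) than geography (20.7%); facilities differ while parallel
bioreactors within a facility do not; and the seasonal classifier recovers
exactly the bioreactors that were given an annual cycle.

The same analyses are scriptable through the `distdecay` CLI (`synth`,
`decay`, `stats`, `temporal`, `run`) or the one-shot pipeline:

```
distdecay synth study --seed 1 --out study/
distdecay run --config pipeline.yaml
```

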