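# humpback-assess

Bayesian state-space stock assessment of the western South Atlantic (WSA)
humpback whale (*Megaptera novaeangliae*), the population that breeds off
Brazil and was whaled almost to extinction by the mid-twentieth century.
The package is for population ecologists and stock-assessment practitioners
who have a historical removals series plus intermittent abundance and/or
growth-rate estimates and want posterior trajectories, carrying capacity and
depletion levels for a depleted, recovering population.

## The model

The process model is a deterministic generalized-logistic (Pella–Tomlinson)
surplus-production equation with known annual removals:

```
N[t+1] = N[t] + N[t] · r_max · (1 − (N[t]/K)^z) − C[t]
```

with `N[t]` population size in year `t`, `r_max` the maximum net recruitment
rate, `K` carrying capacity (the 1901 population, assumed unexploited before
then), `C[t]` the catch, and shape `z = 2.39` fixed so that net recruitment
peaks at 0.6 K.  The observation model treats abundance estimates as
lognormal around `ln N[t]` and interval growth-rate estimates
`r[x,y] = (ln N[y] − ln N[x])/(y − x)` as normal, with variances fixed by the
published CVs.

Two parameters are sampled — `N_2005 ~ U(500, 22000)` and
`r_max ~ U(0, 0.106)` — and each pair is mapped to a unique `K` by *backward
projection*: bisection for the 1901 population whose forward projection
through the catches reaches the drawn `N_2005`.  Inference is by random-walk
Metropolis MCMC (bivariate-normal proposal tuned to 20–40% acceptance; by
default 3 dispersed chains × 500,000 iterations after 20,000 burn-in, thinned
by 50), with Gelman–Rubin R̂ convergence diagnostics.  Named scenarios
(`base_case`, `updated`, `sa1`–`sa5`) select which observations enter the
likelihood.

## Worked example

The repository ships a fully synthetic study (`data/synthetic_*`): a
trapezoid catch pulse (total 43,350 whales over 1904–1965) generated from
truth `r_max = 0.08`, `K = 21,000`, which drives the population to a minimum
of 526 whales in 1964, plus one observation set drawn at the published survey
CVs.  Fitting the `updated` scenario:

```
assess run --scenario updated --catches data/synthetic_catches.csv \
    --observations data/synthetic_observations.csv \
    --seed 12 --out out/ --n-burn 5000 --n-iter 50000 --thin 50
```

prints (posterior median, mean, 2.5%, 97.5%):

```
                         median          mean         lo2.5        hi97.5    year
quantity
r_max                  0.088250      0.087270      0.063414      0.104923     NaN
K                  19878.072018  20120.202800  17938.278407  23705.257510     NaN
N_min                409.203433    465.538423    234.036145   1010.396413  1964.0
max_depletion          0.020651      0.022550      0.012921      0.042984  1964.0
current_depletion      0.947226      0.935251      0.829916      0.984465  2019.0
N_current          18751.493186  18754.859566  17602.432964  20092.406986  2019.0
```

Read: carrying capacity ≈ 19,900 whales (truth 21,000 inside the interval),
the population bottomed out near 2% of K in 1964, and by 2019 had recovered
to ≈ 95% of K.  `out/` also receives the retained draws, per-year trajectory
quantiles and a convergence report (R̂ < 1.01 here, acceptance ≈ 0.31).

The numbered scripts under `analysis/` run the full narrative: simulate the
study data (01), derive the implied prior on K (02), fit and compare all
seven data-inclusion scenarios (03 — the `updated` fit's mean 95% band width
is 2,677 whales versus 7,509 for `base_case`, and among the single-change
sensitivity runs the precise 2002–2011 growth rate gives the largest
precision gain), and measure frequentist parameter recovery (04 — 95%
interval coverage 0.96 for both `r_max` and `K` over 50 replicates).

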