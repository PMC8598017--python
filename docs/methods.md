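# Methods

## Process model

Population dynamics follow a density-dependent, sex- and age-aggregated
generalized-logistic (Pella–Tomlinson) equation applied on an annual step:

    N[t+1] = N[t] + N[t] · r_max · (1 − (N[t]/K)^z) − C[t]

Catch `C[t]` is treated as known without error and is subtracted in the same
annual update as growth, exactly as the discrete equation is written — no
within-year ordering refinement.  The shape parameter is fixed at `z = 2.39`,
which places the maximum of net recruitment at `(1/(z+1))^(1/z) = 0.60` of
carrying capacity.  The projection runs from 1901 (the onset of modern
whaling on this stock, with the population assumed at carrying capacity,
`N[1901] = K`) to 2040, with zero catch in years beyond the recorded series.
The process is deterministic: a parameter pair determines a unique
trajectory, so all process uncertainty in the posterior comes from parameter
uncertainty.

**Positivity floor.** A trajectory is flagged invalid if any `N[t] ≤ 1`
whale.  The likelihood involves `ln N[t]`, so a floor is needed; one animal
is far below the population's genetic minimum (≈ 264, four times the 66
observed mtDNA haplotypes) and therefore never truncates a biologically
plausible trajectory.  Invalid trajectories carry zero likelihood (−∞
log-posterior) rather than raising, so the sampler simply rejects them.

## Observation model

* Abundance estimates: `N̂[t] ~ Lognormal(ln N[t], σ²_log)`.  The published
  uncertainty is a CV; the exact lognormal relation `σ²_log = ln(1 + CV²)`
  is the default conversion, with the common approximation `σ_log = CV`
  available as a configuration switch (`log_sigma_method="approx"`).  For
  the CVs here (≤ 0.17) the two differ by under 1.5%.
* Growth-rate estimates over years `x < y`:
  `r̂ ~ Normal((ln N[y] − ln N[x])/(y − x), (r̂ · CV)²)`.  The variance is a
  plug-in from the observation itself and is held fixed (known-variance
  contract); the model rate uses the annual `N` values directly, with no
  mid-year interpolation.

Observation terms are independent, so the total log-likelihood is their sum.
The compiled (numba) likelihood used inside the sampler is checked in the
test suite against an independent scipy.stats implementation.

## Priors and the implied prior on K

`N_2005 ~ Uniform(500, 22000)` and `r_max ~ Uniform(0, 0.106)` (the upper
bound is the maximum plausible growth rate for the species).  The pair
`(N_2005, r_max)` determines `K` by backward projection: bisection on
`K ∈ [1, 500000]` for the value whose forward projection hits the drawn
`N_2005`, to a tolerance of 0.1 whale (far below observation error) or 100
iterations.  The forward map `K → N_2005` is monotone (verified empirically
on a grid, and by a forward-consistency assertion on posterior draws); if
the bracket does not straddle the target, or no valid trajectory reaches it,
the draw is recorded as a failure and carries zero posterior density.  The
prior induced on `K` by pushing 10,000 prior draws through this map is the
"implied prior"; with a depleting catch history it is shifted well above the
`N_2005` bounds and couples `K` to `r_max`.  The prior is parameterized on
`(N_2005, r_max)` in every scenario, including those that exclude the 2005
abundance datum from the likelihood; a direct prior on `K` is out of scope.

## Sampling

Random-walk Metropolis on `(N_2005, r_max)` with a bivariate-normal proposal
centred on the current value.  Production defaults: 20,000 burn-in
iterations, 500,000 sampling iterations thinned by 50, three chains started
from dispersed values (`N_2005 ∈ {4250, 6250, 8250}`,
`r_max ∈ {0.01, 0.07, 0.100}`), giving 30,000 retained draws.  Each chain
draws from its own RNG stream derived from the master seed by a fixed
offset, so runs are bit-reproducible.

**Proposal tuning.** The proposal covariance starts from a diagonal matrix
proportional to the squared prior ranges and is rescaled by short pilot
chains: halve the scale when acceptance falls below 0.2, double it above
0.4, and once both sides of the band have been seen, bisect in log space.
Tuning happens entirely before the production run and the covariance is then
frozen, keeping the Markov kernel time-homogeneous; the tuned covariance and
realized acceptance rates are logged and written to the run metadata rather
than hard-coded.  Proposals landing outside the prior box are rejected via a
−∞ posterior (no reflection).

**Convergence.** The classic Gelman–Rubin PSRF,
`R̂ = sqrt(((n−1)/n · W + (1 + 1/m) · B/n) / W)`, is computed for `r_max`,
`N_2005` and `K`; convergence is declared when all `R̂ < 1.1` (the
conventional cutoff).  For identical chains this statistic equals
`sqrt((n−1)/n)`, i.e. 1 to within 10⁻³ at the chain lengths used.

## Scenarios

Seven data-inclusion recipes share one observation pool, one prior and one
sampler configuration; only the included observations differ (base case:
2005 abundance + 1995–1998 growth; updated: 2008 and 2012 abundance + both
growth rates; sa1–sa4: single-change variants; sa5: catches only).  Proposal
tuning is rerun per scenario, since the posterior scale changes with the
data included.

## Synthetic study conditions

The generator produces the three inputs the assessment needs from known
ground truth, so the whole pipeline is testable without any external data.

* **Catches**: a deterministic trapezoid pulse — zero before onset, linear
  ramp to a peak, plateau, linear ramp back to zero.  Defaults (onset 1904,
  ramp-up 6 yr, peak 1,275 whales/yr, ramp-down 50 yr, end 1965; truth
  `r_max = 0.08`, `K = 21,000`) deplete the population to 526 whales in 1964
  — a few hundred animals at mid-century, as in the historical trajectory —
  and release it in time for the survey era, giving `N_2005 ≈ 10,800`.  If a
  profile would drive the truth below the positivity floor the peak is
  scaled down by 10% until viable.
* **Observations**: drawn from exactly the error models the likelihood
  assumes, at the study's survey design (abundance 2005/2008/2012 with CVs
  0.17/0.084/0.071; growth 1995–1998 and 2002–2011 with CVs 0.446/0.115).
  Abundance is lognormal with `σ²_log = ln(1 + CV²)`.  Growth is normal with
  the design sd = true rate × CV; the CV recorded on the simulated
  observation is sd/|estimate|, so the fit-time plug-in `σ = r̂ · CV`
  recovers exactly the design sd.  This is a deliberate simulator choice: a
  survey's reported uncertainty reflects its sampling design, not the luck
  of its point estimate, and recording the design CV verbatim would let a
  near-zero draw from the wide 1995–1998 design (CV 0.446) claim absurd
  precision (e.g. −0.007 ± 0.003), creating a spurious posterior mode near
  `r_max ≈ 0.005, K ≈ 45,000` and breaking interval calibration.  With the
  design-sd convention the generating and fitting models agree and 95%
  credible intervals attain ≈ 95% frequentist coverage.

What the synthetic data do **not** emulate: the magnitude and irregular
year-to-year structure of the historical removals (the real series has far
larger early catches, which is why its implied prior on `K` is much tighter
than the synthetic one), spatial survey design, sex/age structure, and
struck-and-lost corrections.  Passing tests therefore demonstrate that the
estimator recovers known truth under the assumed error structure, not that
the historical data satisfy those assumptions.

## Reporting

Summaries are equal-tailed: median, mean, and 2.5%/97.5% quantiles, using
linear interpolation of order statistics (numpy's default quantile rule,
fixed so test oracles are stable).  The minimum-population year is chosen
globally as the year with the smallest per-year posterior median; `N_min`
and maximum depletion then summarize per-draw values at that fixed year
(a per-draw-minimum variant is available behind a flag, and is never larger).
Current depletion is `N_2019 / K` per draw.

## Problem sizes and numerical choices

Reduced runs are used throughout the scripts and tests: 3 × 50,000
iterations (thin 50) in the analysis scripts and 3 × 10,000 (thin 10) in the
test suite, chosen because posterior medians under these settings agree with
far longer runs well inside every tolerance asserted; the parameter-recovery
experiment uses 50 replicates × 3 chains × 6,000 iterations.  Bisection
tolerance 0.1 whale; positivity floor 1 whale; ties in the minimum-median
year break to the earliest year.

## Known limitations

* The process model is deterministic (no process noise) and `K` is constant
  over time; non-whaling anthropogenic mortality is ignored, which biases
  current-depletion estimates optimistic.
* Catches are assumed exact; the historical series is itself an allocation
  hypothesis.
* The posterior for `K` is strongly shaped by the implied prior whenever the
  data are sparse; with catches only (sa5) the posterior is essentially that
  prior.
* The `r_max ≤ 0.106` prior bound truncates the posterior when the data
  favour fast growth; alternatives (e.g. 0.118) are configurable but not the
  default.
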