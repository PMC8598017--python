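"""Observation model: likelihood of survey data given a population trajectory.

Two kinds of observations enter the likelihood, both with variances fixed by
the observation itself (known-variance contract):

* absolute abundance estimates, assumed lognormal around the true size:
  ``N_hat_t ~ Lognormal(ln N_t, sig2_log)``, with the log-scale variance
  derived from the published CV;
* interval growth-rate estimates, assumed normal around the model rate
  ``r_{x,y} = (ln N_y - ln N_x) / (y - x)`` with standard deviation
  ``estimate * CV``.

Catches are error-free and enter the process model, not the likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dynamics import CatchSeries, Trajectory

#: How to turn a CV into the lognormal log-scale sigma. "exact" uses the
#: exact lognormal relation sig2_log = ln(1 + CV^2); "approx" uses sigma = CV
#: (the two differ by <1.5% for CV <= 0.17).
LOG_SIGMA_METHODS = ("exact", "approx")


def log_variance_from_cv(cv: float, method: str = "exact") -> float:
    """Lognormal log-scale variance implied by a coefficient of variation."""
    if method == "exact":
        return math.log1p(cv * cv)
    if method == "approx":
        return cv * cv
    raise ValueError(f"unknown log-sigma method {method!r}")


@dataclass(frozen=True)
class AbundanceObs:
    """Absolute abundance estimate for one year, with its CV."""

    year: int
    estimate: float
    cv: float

    def __post_init__(self) -> None:
        if not (self.estimate > 0):
            raise ValueError("abundance estimate must be positive")
        if not (self.cv > 0):
            raise ValueError("abundance CV must be positive")


@dataclass(frozen=True)
class GrowthObs:
    """Annual growth-rate estimate over the interval [year_start, year_end]."""

    year_start: int
    year_end: int
    estimate: float
    cv: float

    def __post_init__(self) -> None:
        if self.year_end <= self.year_start:
            raise ValueError("growth interval must have year_end > year_start")
        if not (self.cv > 0):
            raise ValueError("growth CV must be positive")
        if self.estimate == 0:
            raise ValueError("growth estimate of exactly 0 gives zero variance")

    @property
    def sd(self) -> float:
        """Observation standard deviation, fixed as estimate * CV."""
        return abs(self.estimate) * self.cv


@dataclass(frozen=True)
class Dataset:
    """Catch series plus the observations entering the likelihood."""

    catches: CatchSeries
    abundance_obs: tuple[AbundanceObs, ...] = ()
    growth_obs: tuple[GrowthObs, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "abundance_obs", tuple(self.abundance_obs))
        object.__setattr__(self, "growth_obs", tuple(self.growth_obs))
        for ob in self.abundance_obs:
            if ob.year < self.catches.start_year:
                raise ValueError(f"abundance year {ob.year} precedes the catch series")
        for ob in self.growth_obs:
            if ob.year_start < self.catches.start_year:
                raise ValueError(
                    f"growth interval start {ob.year_start} precedes the catch series"
                )

    @property
    def n_obs(self) -> int:
        return len(self.abundance_obs) + len(self.growth_obs)


def model_growth_rate(traj: Trajectory, x: int, y: int) -> float:
    """Model annual growth rate between years x < y: (ln N_y - ln N_x)/(y - x)."""
    if y <= x:
        raise ValueError("growth interval must have y > x")
    if not traj.valid:
        raise ValueError("growth rate undefined on an invalid trajectory")
    nx = traj.population(x)
    ny = traj.population(y)
    return (math.log(ny) - math.log(nx)) / (y - x)


def loglik_growth(obs: GrowthObs, traj: Trajectory) -> float:
    """Normal log-density of the observed rate around the model rate."""
    mean = model_growth_rate(traj, obs.year_start, obs.year_end)
    return float(stats.norm.logpdf(obs.estimate, loc=mean, scale=obs.sd))


def loglik_abundance(
    obs: AbundanceObs, traj: Trajectory, log_sigma_method: str = "exact"
) -> float:
    """Lognormal log-density of the observed abundance around ln(N_year)."""
    if not traj.valid:
        return -np.inf
    n_t = traj.population(obs.year)
    if n_t <= 0:
        return -np.inf
    sigma = math.sqrt(log_variance_from_cv(obs.cv, log_sigma_method))
    return float(stats.lognorm.logpdf(obs.estimate, s=sigma, scale=n_t))


def total_loglik(
    data: Dataset, traj: Trajectory, log_sigma_method: str = "exact"
) -> float:
    """Sum of all observation log-likelihood terms; -inf for invalid trajectories."""
    if not traj.valid:
        return -np.inf
    ll = 0.0
    for ab in data.abundance_obs:
        ll += loglik_abundance(ab, traj, log_sigma_method)
    for gr in data.growth_obs:
        ll += loglik_growth(gr, traj)
    return ll


def pack_observations(
    data: Dataset, start_year: int, log_sigma_method: str = "exact"
) -> tuple[np.ndarray, ...]:
    """Flatten observations into the float/int arrays the compiled kernels use."""
    ab_idx = np.array(
        [ob.year - start_year for ob in data.abundance_obs], dtype=np.int64
    )
    ab_log_est = np.array(
        [math.log(ob.estimate) for ob in data.abundance_obs], dtype=float
    )
    ab_sig2 = np.array(
        [log_variance_from_cv(ob.cv, log_sigma_method) for ob in data.abundance_obs],
        dtype=float,
    )
    gr_x = np.array(
        [ob.year_start - start_year for ob in data.growth_obs], dtype=np.int64
    )
    gr_y = np.array(
        [ob.year_end - start_year for ob in data.growth_obs], dtype=np.int64
    )
    gr_est = np.array([ob.estimate for ob in data.growth_obs], dtype=float)
    gr_sd = np.array([ob.sd for ob in data.growth_obs], dtype=float)
    return ab_idx, ab_log_est, ab_sig2, gr_x, gr_y, gr_est, gr_sd
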