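"""Synthetic study conditions: catch histories and observations from known truth.

The generator emulates the structure of the assessment's inputs — a
depletion-then-protection catch pulse followed by modern survey estimates —
from a known (r_max, K) so that the whole pipeline can be exercised and its
frequentist behaviour (bias, interval coverage) measured without any external
data.  Catches follow a deterministic trapezoid pulse: zero before onset, a
linear ramp up to a peak, a plateau, and a linear ramp back to zero by the
end year.  Observations are drawn from the same error models the likelihood
assumes: lognormal abundance around ln N_t at a design CV, and normal growth
rates around the true interval rate with sd = true rate x CV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dynamics import (
    DEFAULT_Z,
    END_YEAR,
    START_YEAR,
    CatchSeries,
    ProcessParams,
    Trajectory,
    project,
)
from .mcmc import MCMCConfig, run_mcmc
from .observations import AbundanceObs, Dataset, GrowthObs, log_variance_from_cv
from .observations import model_growth_rate
from .priors import PriorSpec


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for data generation.

    Defaults mirror the study conditions: carrying capacity near the
    assessment's estimates, recruitment inside the prior box, a catch pulse
    starting shortly after 1901 that drives the population to a few hundred
    animals by mid-century and releases it in the early 1970s, and the
    study's survey design (abundance in 2005/2008/2012, growth over
    1995-1998 and 2002-2011, at the published CVs).
    """

    r_max_true: float = 0.08
    K_true: float = 21_000.0
    z: float = DEFAULT_Z
    onset_year: int = 1904
    peak_catch: float = 1_275.0
    ramp_up: int = 6
    ramp_down: int = 50
    end_catch_year: int = 1965
    start_year: int = START_YEAR
    end_year: int = END_YEAR
    obs_abundance: tuple[tuple[int, float], ...] = (
        (2005, 0.17), (2008, 0.084), (2012, 0.071),
    )
    obs_growth: tuple[tuple[int, int, float], ...] = (
        (1995, 1998, 0.446), (2002, 2011, 0.115),
    )
    seed: int = 20_210

    def __post_init__(self) -> None:
        if not (self.start_year <= self.onset_year < self.end_catch_year):
            raise ValueError("catch pulse must lie inside the modelled period")
        if self.ramp_up < 1 or self.ramp_down < 1:
            raise ValueError("ramp widths must be at least one year")
        if self.peak_catch < 0:
            raise ValueError("peak catch must be non-negative")

    @property
    def params(self) -> ProcessParams:
        # n_ref is filled from the true trajectory when needed
        return ProcessParams(r_max=self.r_max_true, n_ref=self.K_true, z=self.z)


def _trapezoid(truth: SyntheticTruth, peak: float) -> np.ndarray:
    n_years = truth.end_year - truth.start_year + 1
    c = np.zeros(n_years)
    up_end = truth.onset_year + truth.ramp_up  # first plateau year
    down_start = truth.end_catch_year - truth.ramp_down  # last plateau year
    for i in range(n_years):
        year = truth.start_year + i
        if year < truth.onset_year or year > truth.end_catch_year:
            continue
        if year < up_end:
            c[i] = peak * (year - truth.onset_year + 1) / truth.ramp_up
        elif year <= down_start:
            c[i] = peak
        else:
            c[i] = peak * (truth.end_catch_year - year) / truth.ramp_down
    return np.clip(c, 0.0, peak)


def generate_catches(truth: SyntheticTruth, max_rescale: int = 60) -> CatchSeries:
    """Trapezoid-pulse catch series guaranteed to leave the truth viable.

    If the true trajectory would cross the positivity floor, the peak is
    scaled down by 10% repeatedly (the profile shape is preserved) until the
    trajectory is valid; an infeasible profile raises after ``max_rescale``
    attempts.
    """
    peak = truth.peak_catch
    for _ in range(max_rescale + 1):
        series = CatchSeries(truth.start_year, _trapezoid(truth, peak))
        traj = project(truth.params, truth.K_true, series,
                       end_year=truth.end_year)
        if traj.valid:
            return series
        peak *= 0.9
    raise RuntimeError(
        "catch profile remains infeasible after maximum rescaling attempts"
    )


def true_trajectory(truth: SyntheticTruth,
                    catches: CatchSeries | None = None) -> Trajectory:
    """Deterministic trajectory implied by the truth (and its catch series)."""
    if catches is None:
        catches = generate_catches(truth)
    return project(truth.params, truth.K_true, catches, end_year=truth.end_year)


def simulate_observations(
    truth: SyntheticTruth,
    traj: Trajectory,
    rng: np.random.Generator,
    noise: bool = True,
) -> Dataset:
    """Draw one observation set from the design in ``truth`` around ``traj``.

    With ``noise=False`` the observations equal the true values (the CV -> 0
    limit), which is handy for self-consistency checks.
    """
    if not traj.valid:
        raise ValueError("cannot observe an invalid trajectory")
    ab = []
    for year, cv in truth.obs_abundance:
        n_t = traj.population(year)
        if noise:
            sigma = np.sqrt(log_variance_from_cv(cv, "exact"))
            est = float(np.exp(rng.normal(np.log(n_t), sigma)))
        else:
            est = n_t
        ab.append(AbundanceObs(year=year, estimate=est, cv=cv))
    gr = []
    for x, y, cv in truth.obs_growth:
        rate = model_growth_rate(traj, x, y)
        sd = abs(rate) * cv  # the survey design's sampling error
        est = float(rng.normal(rate, sd)) if noise else rate
        if est == 0.0:  # degenerate draw would imply zero variance; nudge
            est = 1e-12
        # A survey's reported uncertainty reflects its design, not the luck
        # of its point estimate, so the recorded CV is sd/|estimate|: the
        # fit-time plug-in sigma = estimate * CV then recovers exactly the
        # design sd (for the noise-free case this is the design CV itself).
        cv_reported = sd / abs(est) if noise else cv
        gr.append(GrowthObs(year_start=x, year_end=y, estimate=est,
                            cv=cv_reported))
    # generate_catches is deterministic given truth, so this is the same
    # (possibly rescaled) series the trajectory was built from
    return Dataset(catches=generate_catches(truth), abundance_obs=tuple(ab),
                   growth_obs=tuple(gr))


def synthetic_pool(truth: SyntheticTruth, seed: int | None = None,
                   noise: bool = True) -> Dataset:
    """Convenience: catches + one observation set drawn from the truth."""
    catches = generate_catches(truth)
    traj = true_trajectory(truth, catches)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    return simulate_observations(truth, traj, rng, noise=noise)


def recovery_experiment(
    truth: SyntheticTruth,
    n_replicates: int,
    mcmc: MCMCConfig,
    prior: PriorSpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate -> fit -> summarize, replicated; reports bias and coverage.

    Each replicate draws a fresh observation set from the truth, fits the
    model, and records posterior medians and 95% equal-tailed intervals for
    r_max and K.  The returned frame has one row per replicate plus
    convenience boolean columns ``covered_rmax`` / ``covered_K``.
    """
    prior = prior or PriorSpec()
    master = np.random.default_rng(truth.seed if seed is None else seed)
    catches = generate_catches(truth)
    traj = true_trajectory(truth, catches)
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(master.integers(2**31 - 1))
        data = Dataset(
            catches=catches,
            abundance_obs=simulate_observations(truth, traj, rng).abundance_obs,
            growth_obs=simulate_observations(truth, traj, rng).growth_obs,
        )
        cfg = replace(mcmc, seed=int(master.integers(2**31 - 1)))
        draws = run_mcmc(data, prior, cfg)
        row = {"replicate": rep}
        for name, col, true_val in (
            ("rmax", "rmax", truth.r_max_true),
            ("K", "K", truth.K_true),
        ):
            vals = draws.params[col].to_numpy()
            lo, med, hi = np.quantile(vals, [0.025, 0.5, 0.975])
            row[f"median_{name}"] = med
            row[f"lo_{name}"] = lo
            row[f"hi_{name}"] = hi
            row[f"bias_{name}"] = med - true_val
            row[f"covered_{name}"] = bool(lo <= true_val <= hi)
        rows.append(row)
    return pd.DataFrame(rows)


def truth_to_json(truth: SyntheticTruth, path) -> None:
    """Write the ground truth as JSON (for provenance of simulated datasets)."""
    payload = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in truth.__dict__.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=list)
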