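"""Deterministic generalized-logistic (Pella-Tomlinson) population dynamics.

The process model is a density-dependent, sex- and age-aggregated surplus
production equation with annual catch removals:

    N[t+1] = N[t] + N[t] * r_max * (1 - (N[t]/K)**z) - C[t]

where ``N[t]`` is population size in year ``t``, ``r_max`` the maximum net
recruitment rate, ``K`` the carrying capacity (identified with the population
size in the first modelled year, 1901, assuming the stock was unexploited
before then), ``z`` the shape parameter and ``C[t]`` the known catch.  With
``z = 2.39`` net recruitment peaks at 0.6 K.

Catches are treated as known without error; the process equation is
deterministic, so a parameter pair (r_max, K) maps to a unique trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from . import _kernels

#: Default generalized-logistic shape parameter (net recruitment peaks at 0.6 K).
DEFAULT_Z = 2.39

#: First modelled year: onset of modern whaling on this stock.
START_YEAR = 1901

#: Final projection year (no catches assumed beyond the series).
END_YEAR = 2040

#: Reference year whose abundance is a sampled parameter.
REF_YEAR = 2005

#: Year used for "current" depletion.
CURRENT_YEAR = 2019

#: A trajectory touching one whale or fewer is biologically dead and would
#: break the log-likelihood; such trajectories are flagged invalid.
POSITIVITY_FLOOR = _kernels.POSITIVITY_FLOOR

#: mtDNA haplotypes observed in this population, and the conservative
#: "four-fold" genetic lower bound on the minimum plausible population size.
MTDNA_HAPLOTYPES = 66
MIN_PLAUSIBLE_POPULATION = 4 * MTDNA_HAPLOTYPES


@dataclass(frozen=True)
class CatchSeries:
    """Contiguous annual removals (whales killed), known without error.

    Parameters
    ----------
    start_year
        Calendar year of the first catch entry.
    catches
        One non-negative value per year from ``start_year`` with no gaps.
    """

    start_year: int
    catches: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.catches, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("catches must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("catches must be finite")
        if np.any(arr < 0):
            raise ValueError("catches must be non-negative")
        object.__setattr__(self, "catches", arr)

    def __len__(self) -> int:
        return self.catches.size

    @property
    def end_year(self) -> int:
        return self.start_year + len(self) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def total(self) -> float:
        return float(self.catches.sum())

    def catch_in(self, year: int) -> float:
        """Catch in ``year``; zero outside the series (future years)."""
        if year < self.start_year:
            raise ValueError(f"year {year} precedes the catch series")
        i = year - self.start_year
        return float(self.catches[i]) if i < len(self) else 0.0


@dataclass(frozen=True)
class ProcessParams:
    """Sampled process parameters: (r_max, population size in the reference year)."""

    r_max: float
    n_ref: float
    z: float = DEFAULT_Z
    ref_year: int = REF_YEAR

    def __post_init__(self) -> None:
        if not (self.z > 0):
            raise ValueError("z must be positive")
        if not (self.r_max >= 0):
            raise ValueError("r_max must be non-negative")
        if not (self.n_ref > 0):
            raise ValueError("n_ref must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Deterministic annual population sizes from ``start_year`` onwards.

    ``N[0]`` equals the carrying capacity ``K``.  ``valid`` is False when the
    population was driven to or below the positivity floor at any point, in
    which case the trajectory carries zero likelihood.
    """

    start_year: int
    N: np.ndarray
    K: float
    valid: bool = True

    @property
    def end_year(self) -> int:
        return self.start_year + self.N.size - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def index(self, year: int) -> int:
        i = int(year) - self.start_year
        if not (0 <= i < self.N.size):
            raise ValueError(
                f"year {year} outside trajectory span "
                f"{self.start_year}-{self.end_year}"
            )
        return i

    def population(self, year: int) -> float:
        return float(self.N[self.index(year)])


def step(n_t: float, r_max: float, K: float, z: float, c_t: float) -> float:
    """One annual update of the generalized-logistic equation.

    Pure arithmetic with no clamping: the result may be negative under
    over-catch; validity is judged by the caller.
    """
    vals = (n_t, r_max, K, z, c_t)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("non-finite input to step()")
    if K <= 0:
        raise ValueError("K must be positive")
    if c_t < 0:
        raise ValueError("catch must be non-negative")
    return n_t + n_t * r_max * (1.0 - (n_t / K) ** z) - c_t


def msy_level(z: float) -> float:
    """Relative population level (fraction of K) maximizing net recruitment.

    Net recruitment ``N * r_max * (1 - (N/K)**z)`` is maximized at
    ``N/K = (1/(z+1))**(1/z)``; for z = 2.39 this is 0.60 K.
    """
    if not (z > 0) or not math.isfinite(z):
        raise ValueError("z must be positive and finite")
    return (1.0 / (z + 1.0)) ** (1.0 / z)


def project(
    params: ProcessParams,
    K: float,
    catches: CatchSeries,
    start_year: int | None = None,
    end_year: int = END_YEAR,
) -> Trajectory:
    """Project the population from ``K`` at ``start_year`` through the catches.

    Catch is zero for years beyond the series.  The trajectory is flagged
    invalid (not raised) if the population touches the positivity floor;
    downstream this signals zero likelihood.
    """
    if K <= 0 or not math.isfinite(K):
        raise ValueError("K must be positive and finite")
    if start_year is None:
        start_year = catches.start_year
    if start_year < catches.start_year:
        raise ValueError("projection cannot start before the catch series")
    if end_year < start_year:
        raise ValueError("end_year precedes start_year")
    offset = start_year - catches.start_year
    n_years = end_year - start_year + 1
    N, valid = _kernels.project_kernel(
        float(K), float(params.r_max), float(params.z),
        catches.catches[offset:], n_years,
    )
    return Trajectory(start_year=start_year, N=N, K=float(K), valid=bool(valid))


def depletion(traj: Trajectory, year: int) -> float:
    """Population in ``year`` relative to carrying capacity, N_year / K."""
    return traj.population(year) / traj.K


def min_population_year(
    per_year_medians: Iterable[tuple[int, float]],
) -> tuple[int, float]:
    """Year with the smallest median population; ties go to the earliest year."""
    pairs = list(per_year_medians)
    if not pairs:
        raise ValueError("empty per-year median sequence")
    years = np.array([int(y) for y, _ in pairs])
    vals = np.array([float(v) for _, v in pairs])
    order = np.lexsort((years, vals))  # smallest value first, earliest year on ties
    i = order[0]
    return int(years[i]), float(vals[i])
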