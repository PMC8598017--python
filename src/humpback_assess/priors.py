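"""Priors on (N_2005, r_max) and the implied prior on carrying capacity.

The sampled parameters carry independent uniform priors: population size in
the 2005 reference year on (500, 22000) and the maximum net recruitment rate
on (0, 0.106), the maximum plausible growth rate for the species.  Because
the process model is deterministic and catches are known, each draw implies a
unique carrying capacity K (the 1901 population): "backward projection" finds,
by bisection, the K whose forward projection through the catch series hits the
drawn N_2005.  Pushing prior draws through this map Monte-Carlo-derives the
implied prior on K, which for a depleting catch history is far more
concentrated than either marginal prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .dynamics import DEFAULT_Z, REF_YEAR, CatchSeries, ProcessParams

#: Bisection bracket for K (whales) and convergence tolerance on N_ref.
BISECTION_BRACKET = (1.0, 500_000.0)
BISECTION_TOL = 0.1
BISECTION_MAX_ITER = 100


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior bounds for the sampled pair."""

    n2005_bounds: tuple[float, float] = (500.0, 22_000.0)
    rmax_bounds: tuple[float, float] = (0.0, 0.106)

    def __post_init__(self) -> None:
        for lo, hi in (self.n2005_bounds, self.rmax_bounds):
            if not lo < hi:
                raise ValueError("prior bounds must satisfy lower < upper")

    def contains(self, params: ProcessParams) -> bool:
        n_lo, n_hi = self.n2005_bounds
        r_lo, r_hi = self.rmax_bounds
        return n_lo <= params.n_ref <= n_hi and r_lo <= params.r_max <= r_hi


def sample_prior(
    spec: PriorSpec, rng: np.random.Generator, z: float = DEFAULT_Z
) -> ProcessParams:
    """One independent uniform draw of (N_2005, r_max)."""
    n_ref = rng.uniform(*spec.n2005_bounds)
    r_max = rng.uniform(*spec.rmax_bounds)
    return ProcessParams(r_max=r_max, n_ref=n_ref, z=z)


def backproject_K(
    r_max: float,
    n_2005: float,
    catches: CatchSeries,
    z: float = DEFAULT_Z,
    ref_year: int = REF_YEAR,
    bracket: tuple[float, float] = BISECTION_BRACKET,
    tol: float = BISECTION_TOL,
    max_iter: int = BISECTION_MAX_ITER,
) -> float | None:
    """Carrying capacity whose forward projection reaches n_2005 in ref_year.

    Returns None when no valid K in the bracket reproduces the target (for
    example because every candidate trajectory crashes through the positivity
    floor), signalling zero posterior density for that parameter pair.
    """
    ref_idx = ref_year - catches.start_year
    if ref_idx <= 0:
        raise ValueError("reference year must fall after the catch series start")
    K = _kernels.backproject_kernel(
        float(r_max), float(n_2005), float(z), catches.catches,
        ref_idx, float(bracket[0]), float(bracket[1]), float(tol), int(max_iter),
    )
    return None if np.isnan(K) else float(K)


def implied_K_prior(
    spec: PriorSpec,
    catches: CatchSeries,
    n: int = 10_000,
    rng: np.random.Generator | None = None,
    z: float = DEFAULT_Z,
) -> tuple[np.ndarray, float]:
    """Monte-Carlo sample of the prior induced on K by backward projection.

    Draws ``n`` parameter pairs from the priors, backprojects each, records
    and excludes failures.  Returns (K sample, failure fraction).
    """
    if rng is None:
        rng = np.random.default_rng()
    n_lo, n_hi = spec.n2005_bounds
    r_lo, r_hi = spec.rmax_bounds
    n_refs = rng.uniform(n_lo, n_hi, size=n)
    r_maxs = rng.uniform(r_lo, r_hi, size=n)
    ref_idx = REF_YEAR - catches.start_year
    ks = np.empty(n)
    for i in range(n):
        ks[i] = _kernels.backproject_kernel(
            r_maxs[i], n_refs[i], z, catches.catches, ref_idx,
            BISECTION_BRACKET[0], BISECTION_BRACKET[1],
            BISECTION_TOL, BISECTION_MAX_ITER,
        )
    ok = ~np.isnan(ks)
    return ks[ok], float(1.0 - ok.mean())
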