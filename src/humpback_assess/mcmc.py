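"""Metropolis sampler over (N_2005, r_max) and convergence diagnostics.

A simple random-walk Metropolis algorithm with a bivariate-normal proposal
centred on the current value samples the two free parameters.  The prior is
flat inside its box, so the unnormalized log-posterior is the observation
log-likelihood of the trajectory implied by each pair (via backprojection of
K), and -inf outside the box or when backprojection fails.  Proposal scale is
tuned by pilot rounds before sampling (the kernel is frozen afterwards) to
keep acceptance inside the 0.2-0.4 band.  Defaults: 20,000 burn-in
iterations, 500,000 sampling iterations thinned by 50, three chains from
dispersed start values, giving 30,000 retained draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .dynamics import DEFAULT_Z, END_YEAR, ProcessParams
from .observations import Dataset, pack_observations, total_loglik
from .priors import (
    BISECTION_BRACKET,
    BISECTION_MAX_ITER,
    BISECTION_TOL,
    PriorSpec,
    backproject_K,
)
from .dynamics import project

logger = logging.getLogger(__name__)

#: Start values used in the study: dispersed so the chains have to agree.
DEFAULT_START_VALUES = ((4250.0, 0.01), (6250.0, 0.07), (8250.0, 0.100))

#: Per-chain seed offset (chain i uses seed + i * CHAIN_SEED_STRIDE).
CHAIN_SEED_STRIDE = 1_000_003


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; defaults reproduce the study's computation."""

    n_burn: int = 20_000
    n_iter: int = 500_000
    thin: int = 50
    n_chains: int = 3
    proposal_cov: np.ndarray | None = None  # tuned when None
    start_values: tuple[tuple[float, float], ...] = DEFAULT_START_VALUES
    seed: int = 1
    target_acceptance: tuple[float, float] = (0.2, 0.4)
    end_year: int = END_YEAR
    z: float = DEFAULT_Z
    log_sigma_method: str = "exact"

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if len(self.start_values) < self.n_chains:
            raise ValueError("need a start value per chain")
        if self.thin < 1 or self.n_iter < self.thin:
            raise ValueError("thinning must keep at least one draw")
        if self.proposal_cov is not None:
            cov = np.asarray(self.proposal_cov, dtype=float)
            if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
                raise ValueError("proposal_cov must be symmetric 2x2")
            np.linalg.cholesky(cov)  # raises if not positive definite
            object.__setattr__(self, "proposal_cov", cov)


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained draws from all chains plus derived per-year populations."""

    params: pd.DataFrame  # columns: chain, iter, n2005, rmax, K
    N: np.ndarray  # (n_draws, n_years) annual population sizes
    start_year: int
    acceptance: tuple[float, ...]
    rhat: dict[str, float] = field(default_factory=dict)
    proposal_cov: np.ndarray | None = None
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return len(self.params)

    @property
    def end_year(self) -> int:
        return self.start_year + self.N.shape[1] - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def year_index(self, year: int) -> int:
        i = int(year) - self.start_year
        if not (0 <= i < self.N.shape[1]):
            raise ValueError(f"year {year} outside {self.start_year}-{self.end_year}")
        return i

    def population_draws(self, year: int) -> np.ndarray:
        return self.N[:, self.year_index(year)]

    def converged(self, threshold: float = 1.1) -> bool:
        return bool(self.rhat) and all(r < threshold for r in self.rhat.values())


def log_posterior(
    params: ProcessParams,
    data: Dataset,
    spec: PriorSpec,
    end_year: int = END_YEAR,
    log_sigma_method: str = "exact",
) -> float:
    """Unnormalized log-posterior of one (N_2005, r_max) pair.

    Flat prior inside the box, so this equals the total observation
    log-likelihood of the implied trajectory; -inf outside the box, on
    backprojection failure, or for an invalid trajectory.
    """
    if not spec.contains(params):
        return -np.inf
    K = backproject_K(params.r_max, params.n_ref, data.catches, z=params.z)
    if K is None:
        return -np.inf
    traj = project(params, K, data.catches, end_year=end_year)
    if not traj.valid:
        return -np.inf
    return total_loglik(data, traj, log_sigma_method)


def _kernel_args(data: Dataset, spec: PriorSpec, config: MCMCConfig):
    start_year = data.catches.start_year
    n_years = config.end_year - start_year + 1
    ref_idx = 2005 - start_year
    packed = pack_observations(data, start_year, config.log_sigma_method)
    return (
        spec.n2005_bounds[0], spec.n2005_bounds[1],
        spec.rmax_bounds[0], spec.rmax_bounds[1],
        config.z, data.catches.catches, n_years, ref_idx,
        *packed,
        BISECTION_BRACKET[0], BISECTION_BRACKET[1],
        BISECTION_TOL, BISECTION_MAX_ITER,
    )


def _chain_seed(master_seed: int, chain_id: int) -> int:
    return int((master_seed + chain_id * CHAIN_SEED_STRIDE) % (2**31 - 1))


def run_chain(
    data: Dataset,
    spec: PriorSpec,
    config: MCMCConfig,
    chain_id: int = 0,
    proposal_cov: np.ndarray | None = None,
    n_burn: int | None = None,
    n_iter: int | None = None,
    log_target: Callable[[float, float], float] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Run one Metropolis chain; returns (draws, N matrix, acceptance rate).

    ``draws`` has columns (N_2005, r_max, K) for the retained (post-burn,
    thinned) iterations.  ``log_target`` substitutes an arbitrary bivariate
    log-density for the model posterior (used for sampler validation); with a
    substituted target the K column and N matrix are NaN.
    """
    cov = proposal_cov if proposal_cov is not None else config.proposal_cov
    if cov is None:
        raise ValueError("proposal covariance not set; run tune_proposal first")
    L = np.linalg.cholesky(np.asarray(cov, dtype=float))
    start = config.start_values[chain_id]
    seed = _chain_seed(config.seed, chain_id)
    burn = config.n_burn if n_burn is None else n_burn
    iters = config.n_iter if n_iter is None else n_iter
    if log_target is not None:
        return _python_chain(seed, start, burn, iters, config.thin, L, log_target)
    args = _kernel_args(data, spec, config)
    lp0, _ = _kernels.logpost_kernel(start[0], start[1], *args)
    if not np.isfinite(lp0):
        raise ValueError(
            f"chain {chain_id} start value {start} has zero posterior density"
        )
    draws, Nmat, acc = _kernels.metropolis_kernel(
        seed, start[0], start[1], burn, iters, config.thin,
        L[0, 0], L[1, 0], L[1, 1], *args,
    )
    return draws, Nmat, float(acc)


def _python_chain(seed, start, n_burn, n_iter, thin, L, log_target):
    """Pure-Python Metropolis mirror of the compiled kernel for generic targets."""
    rng = np.random.RandomState(seed)
    cur = np.array(start, dtype=float)
    cur_lp = log_target(cur[0], cur[1])
    if not np.isfinite(cur_lp):
        raise ValueError("start value has zero target density")
    n_keep = n_iter // thin
    draws = np.full((n_keep, 3), np.nan)
    kept = 0
    accepted = 0
    for it in range(n_burn + n_iter):
        z = rng.standard_normal(2)
        prop = cur + L @ z
        lp = log_target(prop[0], prop[1])
        if math.log(rng.random_sample()) < lp - cur_lp:
            cur, cur_lp = prop, lp
            if it >= n_burn:
                accepted += 1
        if it >= n_burn and (it - n_burn + 1) % thin == 0 and kept < n_keep:
            draws[kept, :2] = cur
            kept += 1
    return draws, np.full((n_keep, 0), np.nan), accepted / n_iter


def proposal_scale_update(scale: float, acceptance: float,
                          band: tuple[float, float] = (0.2, 0.4)) -> float:
    """Pilot-tuning rule: halve the scale when rejection-heavy (acceptance
    below the band), double it when acceptance-heavy, leave it otherwise."""
    lo, hi = band
    if acceptance < lo:
        return scale * 0.5
    if acceptance > hi:
        return scale * 2.0
    return scale


def tune_proposal(
    config: MCMCConfig,
    data: Dataset,
    spec: PriorSpec,
    pilot_iters: int = 2_000,
    max_rounds: int = 20,
) -> np.ndarray:
    """Pilot-run adaptation of the proposal covariance scale.

    Starts from a base covariance proportional to the squared prior ranges and
    repeatedly runs short pilot chains.  While the band is unbracketed the
    scale follows the coarse ``proposal_scale_update`` rule (halve when
    rejection-heavy, double when acceptance-heavy); once scales on both sides
    of the band have been seen it bisects between them in log space.  The
    returned covariance is frozen for the production run, keeping the sampling
    kernel time-homogeneous.  Logs a warning (and returns the best attempt) if
    the band is not reached within ``max_rounds``.
    """
    n_range = spec.n2005_bounds[1] - spec.n2005_bounds[0]
    r_range = spec.rmax_bounds[1] - spec.rmax_bounds[0]
    base = np.diag([(0.05 * n_range) ** 2, (0.05 * r_range) ** 2])
    scale = 1.0
    lo, hi = config.target_acceptance
    mid = 0.5 * (lo + hi)
    best = (np.inf, scale)
    s_small = None  # largest scale seen with acceptance above the band
    s_big = None  # smallest scale seen with acceptance below the band
    for _ in range(max_rounds):
        cov = scale**2 * base
        _, _, acc = run_chain(
            data, spec, config, chain_id=0, proposal_cov=cov,
            n_burn=0, n_iter=pilot_iters,
        )
        if abs(acc - mid) < best[0]:
            best = (abs(acc - mid), scale)
        if lo <= acc <= hi:
            logger.info("proposal tuned: scale=%.4g acceptance=%.3f", scale, acc)
            return cov
        if acc > hi:
            s_small = scale if s_small is None else max(s_small, scale)
        else:
            s_big = scale if s_big is None else min(s_big, scale)
        if s_small is not None and s_big is not None:
            scale = float(np.sqrt(s_small * s_big))
        else:
            scale = proposal_scale_update(scale, acc, (lo, hi))
    logger.warning(
        "proposal tuning did not reach acceptance band %s; using best scale %.4g",
        config.target_acceptance, best[1],
    )
    return best[1] ** 2 * base


def gelman_rubin(chains: Sequence[np.ndarray] | np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor for a scalar quantity.

    ``chains`` is m x n (m >= 2 equal-length chains).  Computes the classic
    PSRF: with within-chain variance W and between-chain variance B/n,
    R-hat = sqrt(((n-1)/n * W + (1 + 1/m) * B/n) / W).
    """
    try:
        arr = np.asarray(chains, dtype=float)
    except ValueError as exc:
        raise ValueError("chains must have equal lengths") from exc
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-D (m chains x n draws) array")
    m, n = arr.shape
    if m < 2:
        raise ValueError("need at least two chains")
    if n < 10:
        raise ValueError("chains too short for a meaningful diagnostic")
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)
    if W == 0:
        return 1.0 if B_over_n == 0 else np.inf
    v_hat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    return float(np.sqrt(v_hat / W))


def run_mcmc(
    data: Dataset,
    spec: PriorSpec,
    config: MCMCConfig,
) -> PosteriorDraws:
    """Tune (if needed), run all chains, combine, and diagnose convergence."""
    cov = config.proposal_cov
    if cov is None:
        cov = tune_proposal(config, data, spec)
    frames = []
    Nmats = []
    acc_rates = []
    per_chain = {"n2005": [], "rmax": [], "K": []}
    for c in range(config.n_chains):
        draws, Nmat, acc = run_chain(data, spec, config, chain_id=c,
                                     proposal_cov=cov)
        df = pd.DataFrame(draws, columns=["n2005", "rmax", "K"])
        df.insert(0, "iter", np.arange(len(df)))
        df.insert(0, "chain", c)
        frames.append(df)
        Nmats.append(Nmat)
        acc_rates.append(acc)
        for k in per_chain:
            per_chain[k].append(df[k].to_numpy())
        logger.info("chain %d: %d retained draws, acceptance %.3f", c, len(df), acc)
    params = pd.concat(frames, ignore_index=True)
    rhat = {}
    if config.n_chains >= 2:
        rhat = {k: gelman_rubin(np.vstack(v)) for k, v in per_chain.items()}
        logger.info("R-hat: %s", rhat)
    return PosteriorDraws(
        params=params,
        N=np.vstack(Nmats),
        start_year=data.catches.start_year,
        acceptance=tuple(acc_rates),
        rhat=rhat,
        proposal_cov=np.asarray(cov, dtype=float),
        seed=config.seed,
    )
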