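"""Numba-compiled inner loops: projection, backprojection, likelihood, Metropolis.

Everything here works on plain float64 arrays so the Metropolis sampler can
evaluate the posterior (a bisection backprojection plus a century-long
projection per proposal) hundreds of thousands of times in seconds.  The
Python-facing modules wrap these kernels in domain types; the observation
module independently recomputes the same log-likelihood terms through
scipy.stats, which the test suite uses as a cross-check of these kernels.
"""

from __future__ import annotations

import numpy as np
from numba import njit

POSITIVITY_FLOOR = 1.0


@njit(cache=True)
def project_kernel(K, r_max, z, catches, n_years):
    """Iterate the generalized-logistic update from N=K for n_years entries.

    Catches beyond the supplied array are zero.  Returns (N, valid); once the
    population touches the positivity floor the remaining entries are zeroed
    and the trajectory is invalid.
    """
    N = np.empty(n_years)
    N[0] = K
    valid = True
    n_c = catches.shape[0]
    for t in range(n_years - 1):
        n = N[t]
        if n <= POSITIVITY_FLOOR:
            valid = False
            N[t + 1] = 0.0
            continue
        c = catches[t] if t < n_c else 0.0
        N[t + 1] = n + n * r_max * (1.0 - (n / K) ** z) - c
    if N[n_years - 1] <= POSITIVITY_FLOOR:
        valid = False
    return N, valid


@njit(cache=True)
def n_ref_kernel(K, r_max, z, catches, ref_idx):
    """Population ref_idx years after the start, or (-1, False) on a crash."""
    n = K
    n_c = catches.shape[0]
    for t in range(ref_idx):
        if n <= POSITIVITY_FLOOR:
            return -1.0, False
        c = catches[t] if t < n_c else 0.0
        n = n + n * r_max * (1.0 - (n / K) ** z) - c
    if n <= POSITIVITY_FLOOR:
        return -1.0, False
    return n, True


@njit(cache=True)
def backproject_kernel(r_max, n_target, z, catches, ref_idx, lo, hi, tol, max_iter):
    """Bisection for the K whose projection hits n_target at ref_idx.

    The forward map K -> N_ref is monotone increasing; a crashed (invalid)
    trajectory is treated as "below target" so bisection moves K upward.
    Returns nan when the bracket does not straddle the target or no valid K
    reaches it within tolerance.
    """
    n_lo, ok_lo = n_ref_kernel(lo, r_max, z, catches, ref_idx)
    f_lo = n_lo - n_target if ok_lo else -1.0
    n_hi, ok_hi = n_ref_kernel(hi, r_max, z, catches, ref_idx)
    f_hi = n_hi - n_target if ok_hi else -1.0
    if f_lo > 0.0 or f_hi < 0.0:
        return np.nan
    if ok_lo and abs(f_lo) < tol:
        return lo
    if ok_hi and abs(f_hi) < tol:
        return hi
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        n_mid, ok = n_ref_kernel(mid, r_max, z, catches, ref_idx)
        f_mid = n_mid - n_target if ok else -1.0
        if ok and abs(f_mid) < tol:
            return mid
        if f_mid < 0.0:
            lo = mid
        else:
            hi = mid
    n_mid, ok = n_ref_kernel(mid, r_max, z, catches, ref_idx)
    if ok and abs(n_mid - n_target) < tol:
        return mid
    return np.nan


@njit(cache=True)
def loglik_kernel(
    N,
    ab_idx, ab_log_est, ab_sig2_log,
    gr_x_idx, gr_y_idx, gr_est, gr_sd,
):
    """Sum of lognormal abundance and normal growth-rate log-densities.

    Abundance: obs ~ Lognormal(ln N_t, sig2_log); growth between years x < y:
    obs ~ Normal((ln N_y - ln N_x)/(y - x), sd^2) with sd fixed by the
    observation (estimate * CV).
    """
    ll = 0.0
    for i in range(ab_idx.shape[0]):
        n_t = N[ab_idx[i]]
        if n_t <= 0.0:
            return -np.inf
        d = ab_log_est[i] - np.log(n_t)
        ll += (
            -ab_log_est[i]
            - 0.5 * np.log(2.0 * np.pi * ab_sig2_log[i])
            - d * d / (2.0 * ab_sig2_log[i])
        )
    for j in range(gr_x_idx.shape[0]):
        nx = N[gr_x_idx[j]]
        ny = N[gr_y_idx[j]]
        if nx <= 0.0 or ny <= 0.0:
            return -np.inf
        rate = (np.log(ny) - np.log(nx)) / (gr_y_idx[j] - gr_x_idx[j])
        d = gr_est[j] - rate
        ll += (
            -0.5 * np.log(2.0 * np.pi * gr_sd[j] * gr_sd[j])
            - d * d / (2.0 * gr_sd[j] * gr_sd[j])
        )
    return ll


@njit(cache=True)
def logpost_kernel(
    n_ref, r_max,
    n_lo, n_hi, r_lo, r_hi,
    z, catches, n_years, ref_idx,
    ab_idx, ab_log_est, ab_sig2_log,
    gr_x_idx, gr_y_idx, gr_est, gr_sd,
    bk_lo, bk_hi, bk_tol, bk_maxit,
):
    """Unnormalized log-posterior over the sampled pair (N_ref, r_max).

    Flat priors inside the box; outside the box, on backprojection failure,
    or on an invalid trajectory the density is zero (-inf).  Returns
    (log-posterior, K).
    """
    if n_ref < n_lo or n_ref > n_hi or r_max < r_lo or r_max > r_hi:
        return -np.inf, np.nan
    K = backproject_kernel(
        r_max, n_ref, z, catches, ref_idx, bk_lo, bk_hi, bk_tol, bk_maxit
    )
    if np.isnan(K):
        return -np.inf, np.nan
    N, valid = project_kernel(K, r_max, z, catches, n_years)
    if not valid:
        return -np.inf, np.nan
    ll = loglik_kernel(
        N, ab_idx, ab_log_est, ab_sig2_log, gr_x_idx, gr_y_idx, gr_est, gr_sd
    )
    return ll, K


@njit(cache=True)
def metropolis_kernel(
    seed,
    n0, r0,
    n_burn, n_iter, thin,
    l11, l21, l22,
    n_lo, n_hi, r_lo, r_hi,
    z, catches, n_years, ref_idx,
    ab_idx, ab_log_est, ab_sig2_log,
    gr_x_idx, gr_y_idx, gr_est, gr_sd,
    bk_lo, bk_hi, bk_tol, bk_maxit,
):
    """Random-walk Metropolis with a fixed bivariate-normal proposal.

    (l11, l21, l22) is the lower Cholesky factor of the proposal covariance.
    Returns (draws[n_keep, 3] of (N_ref, r_max, K), N[n_keep, n_years],
    acceptance rate over post-burn iterations).
    """
    np.random.seed(seed)
    cur_n = n0
    cur_r = r0
    cur_lp, cur_K = logpost_kernel(
        cur_n, cur_r, n_lo, n_hi, r_lo, r_hi, z, catches, n_years, ref_idx,
        ab_idx, ab_log_est, ab_sig2_log, gr_x_idx, gr_y_idx, gr_est, gr_sd,
        bk_lo, bk_hi, bk_tol, bk_maxit,
    )
    n_keep = n_iter // thin
    draws = np.empty((n_keep, 3))
    Nmat = np.empty((n_keep, n_years))
    kept = 0
    accepted = 0
    total = n_burn + n_iter
    for it in range(total):
        z1 = np.random.normal()
        z2 = np.random.normal()
        prop_n = cur_n + l11 * z1
        prop_r = cur_r + l21 * z1 + l22 * z2
        lp, Kp = logpost_kernel(
            prop_n, prop_r, n_lo, n_hi, r_lo, r_hi, z, catches, n_years,
            ref_idx, ab_idx, ab_log_est, ab_sig2_log,
            gr_x_idx, gr_y_idx, gr_est, gr_sd,
            bk_lo, bk_hi, bk_tol, bk_maxit,
        )
        u = np.random.random()
        if np.log(u) < lp - cur_lp:
            cur_n = prop_n
            cur_r = prop_r
            cur_lp = lp
            cur_K = Kp
            if it >= n_burn:
                accepted += 1
        if it >= n_burn and (it - n_burn + 1) % thin == 0 and kept < n_keep:
            draws[kept, 0] = cur_n
            draws[kept, 1] = cur_r
            draws[kept, 2] = cur_K
            N, _ = project_kernel(cur_K, cur_r, z, catches, n_years)
            Nmat[kept, :] = N
            kept += 1
    acc_rate = accepted / n_iter if n_iter > 0 else 0.0
    return draws, Nmat, acc_rate
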