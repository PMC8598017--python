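"""Posterior summaries: parameter table, trajectory quantiles, depletion.

Summaries are equal-tailed: median, mean and the 2.5%/97.5% quantiles, with
quantiles computed by linear interpolation of order statistics (numpy's
default rule).  The minimum-population year is fixed globally as the year
with the smallest per-year posterior median (the study reports a single
year), then per-draw populations at that year are summarized; a per-draw
minimum variant is available behind a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dynamics import CURRENT_YEAR, min_population_year
from .mcmc import PosteriorDraws

_QUANTS = (0.025, 0.5, 0.975)


def _summary_row(vals: np.ndarray) -> dict[str, float]:
    lo, med, hi = np.quantile(vals, _QUANTS)
    return {"median": med, "mean": float(np.mean(vals)), "lo2.5": lo, "hi97.5": hi}


def summarize(
    draws: PosteriorDraws,
    current_year: int = CURRENT_YEAR,
    per_draw_minimum: bool = False,
) -> pd.DataFrame:
    """Posterior summary table for the assessment's headline quantities.

    Rows: r_max, K, N_min (population in the minimum-median year, with its
    year attached), maximum depletion (N in that year / K, per draw), current
    depletion (N_current / K), and N_current.  ``per_draw_minimum`` switches
    N_min and maximum depletion to each draw's own trajectory minimum.
    """
    if draws.n_draws == 0:
        raise ValueError("empty posterior draws")
    K = draws.params["K"].to_numpy()
    rmax = draws.params["rmax"].to_numpy()
    medians = np.median(draws.N, axis=0)
    min_year, _ = min_population_year(zip(draws.years, medians))
    if per_draw_minimum:
        n_min = draws.N.min(axis=1)
    else:
        n_min = draws.population_draws(min_year)
    n_cur = draws.population_draws(current_year)
    rows = {
        "r_max": _summary_row(rmax),
        "K": _summary_row(K),
        "N_min": _summary_row(n_min),
        "max_depletion": _summary_row(n_min / K),
        "current_depletion": _summary_row(n_cur / K),
        "N_current": _summary_row(n_cur),
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "quantity"
    table["year"] = [
        np.nan, np.nan, min_year, min_year, current_year, current_year
    ]
    return table


def trajectory_quantiles(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-year posterior median and equal-tailed 95% band of population size."""
    lo, med, hi = np.quantile(draws.N, _QUANTS, axis=0)
    return pd.DataFrame(
        {"year": draws.years, "median": med, "lo": lo, "hi": hi}
    )


def mean_band_width(draws: PosteriorDraws,
                    year_range: tuple[int, int] | None = None) -> float:
    """Average width of the per-year 95% band, optionally over a year range.

    Used to compare the precision of scenario fits (narrower is better).
    """
    tq = trajectory_quantiles(draws)
    if year_range is not None:
        tq = tq[(tq.year >= year_range[0]) & (tq.year <= year_range[1])]
    return float((tq.hi - tq.lo).mean())


def plot_trajectory(draws: PosteriorDraws, catches=None, path=None, ax=None):
    """Trajectory median and 95% band, with the catch series overlaid."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    tq = trajectory_quantiles(draws)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4.5))
    ax.plot(tq.year, tq["median"], "k-", label="posterior median")
    ax.plot(tq.year, tq.lo, "k--", lw=0.8, label="95% CI")
    ax.plot(tq.year, tq.hi, "k--", lw=0.8)
    if catches is not None:
        ax.plot(catches.years, catches.catches, color="grey", label="catches")
    ax.set_xlabel("year")
    ax.set_ylabel("whales")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
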