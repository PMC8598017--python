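"""File formats, run configuration, and the assessment driver.

Catch series are CSV with header ``year,catch`` (contiguous ascending years,
non-negative catches, parsed strictly).  Observations are CSV with header
``type,year_start,year_end,estimate,cv`` where abundance rows have
``year_start == year_end``.  A best-effort extractor pulls the catch series
out of the published supplementary R code when a user supplies it as plain
text.  ``run_assessment`` ties the pipeline together and writes a
reproducible output bundle.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import CURRENT_YEAR, END_YEAR, CatchSeries
from .mcmc import MCMCConfig, run_mcmc
from .observations import AbundanceObs, Dataset, GrowthObs
from .priors import PriorSpec
from .reporting import summarize, trajectory_quantiles
from .scenarios import SCENARIO_NAMES, build_scenario, study_pool

logger = logging.getLogger(__name__)


def load_catch_series(path) -> CatchSeries:
    """Strictly parse a ``year,catch`` CSV into a CatchSeries."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["year", "catch"]:
        raise ValueError(
            f"{path}: expected header 'year,catch', got {list(df.columns)}"
        )
    try:
        years = df["year"].astype(int).to_numpy()
        catches = df["catch"].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric row: {exc}") from exc
    if len(years) == 0:
        raise ValueError(f"{path}: empty catch series")
    if not np.array_equal(df["year"].to_numpy(dtype=float), years):
        raise ValueError(f"{path}: years must be integers")
    diffs = np.diff(years)
    if np.any(diffs != 1):
        gap_at = int(years[np.argmax(diffs != 1)])
        raise ValueError(f"{path}: year gap after {gap_at} (missing {gap_at + 1})")
    if np.any(catches < 0):
        bad = int(years[np.argmax(catches < 0)])
        raise ValueError(f"{path}: negative catch in {bad}")
    return CatchSeries(start_year=int(years[0]), catches=catches)


def save_catch_series(series: CatchSeries, path) -> None:
    pd.DataFrame({"year": series.years, "catch": series.catches}).to_csv(
        path, index=False
    )


def extract_catch_series_from_r_code(path, start_year: int | None = None
                                     ) -> CatchSeries:
    """Best-effort extraction of a catch vector from supplementary R code.

    Looks for `name <- c(...)` numeric vector assignments (the layout used in
    the published supplementary code, once exported to plain text).  If a
    vector of years (consecutive integers) and an equal-length catch vector
    are both present they are paired; otherwise the longest numeric vector is
    taken as catches starting at ``start_year`` (default 1901).
    """
    text = Path(path).read_text()
    vectors: dict[str, np.ndarray] = {}
    for m in re.finditer(
        r"([A-Za-z._][\w.]*)\s*(?:<-|=)\s*c\(([^()]*)\)", text, re.S
    ):
        body = m.group(2).replace("\n", " ")
        try:
            vals = np.array(
                [float(tok) for tok in re.split(r"[,\s]+", body.strip()) if tok]
            )
        except ValueError:
            continue
        if vals.size:
            vectors[m.group(1)] = vals
    if not vectors:
        raise ValueError(f"{path}: no numeric c(...) vectors found")
    year_vecs = {
        k: v for k, v in vectors.items()
        if v.size > 1 and np.all(np.diff(v) == 1) and np.all(v == v.astype(int))
        and v[0] > 1800
    }
    for yk, yv in year_vecs.items():
        for ck, cv in vectors.items():
            if ck != yk and cv.size == yv.size and np.all(cv >= 0):
                logger.info("paired year vector %r with catch vector %r", yk, ck)
                return CatchSeries(start_year=int(yv[0]), catches=cv)
    name, vals = max(vectors.items(), key=lambda kv: kv[1].size)
    if np.any(vals < 0):
        raise ValueError(f"{path}: candidate catch vector {name!r} has negatives")
    logger.info("using longest vector %r (%d values) as catches", name, vals.size)
    return CatchSeries(start_year=start_year or 1901, catches=vals)


def load_observations(path) -> tuple[tuple[AbundanceObs, ...], tuple[GrowthObs, ...]]:
    """Parse a ``type,year_start,year_end,estimate,cv`` observations CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["type", "year_start", "year_end", "estimate", "cv"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {','.join(expected)}")
    ab, gr = [], []
    for _, row in df.iterrows():
        kind = str(row["type"]).strip().lower()
        x, y = int(row["year_start"]), int(row["year_end"])
        est, cv = float(row["estimate"]), float(row["cv"])
        if kind == "abundance":
            if x != y:
                raise ValueError(f"{path}: abundance rows need year_start == year_end")
            ab.append(AbundanceObs(year=x, estimate=est, cv=cv))
        elif kind == "growth":
            gr.append(GrowthObs(year_start=x, year_end=y, estimate=est, cv=cv))
        else:
            raise ValueError(f"{path}: unknown observation type {kind!r}")
    return tuple(ab), tuple(gr)


def save_observations(abundance, growth, path) -> None:
    rows = [
        {"type": "abundance", "year_start": ob.year, "year_end": ob.year,
         "estimate": ob.estimate, "cv": ob.cv}
        for ob in abundance
    ] + [
        {"type": "growth", "year_start": ob.year_start, "year_end": ob.year_end,
         "estimate": ob.estimate, "cv": ob.cv}
        for ob in growth
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one assessment run."""

    scenario: str
    catches_path: str
    out_dir: str
    observations_path: str | None = None  # None -> the study observation pool
    seed: int = 1
    end_year: int = END_YEAR
    current_year: int = CURRENT_YEAR
    prior: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.scenario!r}")


def load_run_config(path) -> RunConfig:
    """Read a YAML run configuration; MCMC/prior keys override the defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    prior = PriorSpec(**{
        k: tuple(v) for k, v in (raw.pop("prior", {}) or {}).items()
    })
    mcmc_raw = raw.pop("mcmc", {}) or {}
    if "start_values" in mcmc_raw:
        mcmc_raw["start_values"] = tuple(
            tuple(sv) for sv in mcmc_raw["start_values"]
        )
    mcmc = MCMCConfig(seed=raw.get("seed", 1), **mcmc_raw)
    return RunConfig(prior=prior, mcmc=mcmc, **raw)


def run_assessment(config: RunConfig) -> dict:
    """Full pipeline: data -> scenario -> MCMC -> summaries, written to disk.

    Writes draws.csv, summary.csv, trajectory.csv and convergence.json into
    ``config.out_dir`` and returns the bundle in memory.  The metadata JSON
    (seed, tuned proposal covariance, acceptance rates, R-hat values, config
    echo) suffices to reproduce the run exactly.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catches = load_catch_series(config.catches_path)
    if config.observations_path is not None:
        ab, gr = load_observations(config.observations_path)
        pool = Dataset(catches=catches, abundance_obs=ab, growth_obs=gr)
    else:
        pool = study_pool(catches)
    mcmc_cfg = config.mcmc
    if mcmc_cfg.seed != config.seed:
        from dataclasses import replace
        mcmc_cfg = replace(mcmc_cfg, seed=config.seed)
    data, _scenario = build_scenario(config.scenario, pool,
                                     prior=config.prior, mcmc=mcmc_cfg)
    logger.info("scenario %s: %d observations", config.scenario, data.n_obs)
    draws = run_mcmc(data, config.prior, mcmc_cfg)
    summary = summarize(draws, current_year=config.current_year)
    tq = trajectory_quantiles(draws)
    draws.params.to_csv(out / "draws.csv", index=False)
    summary.to_csv(out / "summary.csv")
    tq.to_csv(out / "trajectory.csv", index=False)
    meta = {
        "scenario": config.scenario,
        "seed": config.seed,
        "acceptance": list(draws.acceptance),
        "rhat": draws.rhat,
        "proposal_cov": np.asarray(draws.proposal_cov).tolist(),
        "n_draws": draws.n_draws,
        "converged": draws.converged(),
        "config": {
            "n_burn": mcmc_cfg.n_burn, "n_iter": mcmc_cfg.n_iter,
            "thin": mcmc_cfg.thin, "n_chains": mcmc_cfg.n_chains,
            "start_values": [list(s) for s in mcmc_cfg.start_values],
            "prior_n2005": list(config.prior.n2005_bounds),
            "prior_rmax": list(config.prior.rmax_bounds),
            "end_year": config.end_year,
            "log_sigma_method": mcmc_cfg.log_sigma_method,
        },
    }
    with open(out / "convergence.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    logger.info("run complete: converged=%s rhat=%s", meta["converged"], draws.rhat)
    return {"draws": draws, "summary": summary, "trajectory": tq, "meta": meta}
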