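"""Named data-inclusion scenarios over a common observation pool.

The assessment is rerun under fixed recipes that differ only in which
observations enter the likelihood:

* ``base_case`` — 2005 abundance + 1995-1998 growth (replicates the earlier
  SIR-based assessment);
* ``updated`` — 2008 and 2012 abundances + both growth rates (the 2005 aerial
  estimate is dropped as likely biased low);
* ``sa1`` — base case plus the 2002-2011 growth rate;
* ``sa2``/``sa3`` — base case with the 2005 abundance replaced by 2008 / 2012;
* ``sa4`` — base case with the 2005 abundance replaced by both 2008 and 2012;
* ``sa5`` — catches only (no abundance or growth data).

Priors and sampler settings are shared; only data inclusion varies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mcmc import MCMCConfig
from .observations import AbundanceObs, Dataset, GrowthObs
from .priors import PriorSpec

#: The study's observation pool: abundance estimates (year -> estimate, CV)
#: and interval growth rates ((start, end) -> estimate, CV).
STUDY_ABUNDANCE: dict[int, tuple[float, float]] = {
    2005: (6_251.0, 0.17),
    2008: (14_264.0, 0.084),
    2012: (20_389.0, 0.071),
}
STUDY_GROWTH: dict[tuple[int, int], tuple[float, float]] = {
    (1995, 1998): (0.074, 0.446),
    (2002, 2011): (0.1135, 0.115),
}

#: name -> (abundance years, growth intervals) entering the likelihood.
PRESETS: dict[str, tuple[frozenset[int], frozenset[tuple[int, int]]]] = {
    "base_case": (frozenset({2005}), frozenset({(1995, 1998)})),
    "updated": (frozenset({2008, 2012}), frozenset({(1995, 1998), (2002, 2011)})),
    "sa1": (frozenset({2005}), frozenset({(1995, 1998), (2002, 2011)})),
    "sa2": (frozenset({2008}), frozenset({(1995, 1998)})),
    "sa3": (frozenset({2012}), frozenset({(1995, 1998)})),
    "sa4": (frozenset({2008, 2012}), frozenset({(1995, 1998)})),
    "sa5": (frozenset(), frozenset()),
}

SCENARIO_NAMES = tuple(PRESETS)


@dataclass(frozen=True)
class ScenarioConfig:
    """A named recipe: which observations enter, plus prior and MCMC settings."""

    name: str
    include_abundance: frozenset[int]
    include_growth: frozenset[tuple[int, int]]
    prior: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)


def study_pool(catches) -> Dataset:
    """The full study observation pool bound to a catch series."""
    return Dataset(
        catches=catches,
        abundance_obs=tuple(
            AbundanceObs(year, est, cv)
            for year, (est, cv) in sorted(STUDY_ABUNDANCE.items())
        ),
        growth_obs=tuple(
            GrowthObs(x, y, est, cv)
            for (x, y), (est, cv) in sorted(STUDY_GROWTH.items())
        ),
    )


def build_scenario(
    name: str,
    pool: Dataset,
    prior: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
) -> tuple[Dataset, ScenarioConfig]:
    """Select a preset's observations out of ``pool``.

    Abundance observations are matched by year and growth observations by
    interval, so the pool may hold either the study values or synthetic
    stand-ins with the same design.
    """
    if name not in PRESETS:
        raise KeyError(
            f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}"
        )
    ab_years, gr_intervals = PRESETS[name]
    missing_ab = ab_years - {ob.year for ob in pool.abundance_obs}
    missing_gr = gr_intervals - {
        (ob.year_start, ob.year_end) for ob in pool.growth_obs
    }
    if missing_ab or missing_gr:
        raise ValueError(
            f"pool lacks observations required by {name!r}: "
            f"abundance {sorted(missing_ab)}, growth {sorted(missing_gr)}"
        )
    data = Dataset(
        catches=pool.catches,
        abundance_obs=tuple(
            ob for ob in pool.abundance_obs if ob.year in ab_years
        ),
        growth_obs=tuple(
            ob for ob in pool.growth_obs
            if (ob.year_start, ob.year_end) in gr_intervals
        ),
    )
    cfg = ScenarioConfig(
        name=name,
        include_abundance=ab_years,
        include_growth=gr_intervals,
        prior=prior if prior is not None else PriorSpec(),
        mcmc=mcmc if mcmc is not None else MCMCConfig(),
    )
    return data, cfg
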