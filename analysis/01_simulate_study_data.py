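"""Generate the synthetic study dataset shipped with this project.

The whaling-era catch series used by the original assessment is third-party
supplementary material and is not redistributed here; this script creates a
synthetic stand-in with the same structure — a trapezoid catch pulse that
depletes the population to a few hundred animals by the mid-1960s and then
releases it — plus one observation set drawn from the study's survey design
(abundance in 2005/2008/2012, growth over 1995-1998 and 2002-2011, at the
published CVs).  Ground truth is recorded alongside so later scripts can
measure estimation error.

Writes data/synthetic_catches.csv, data/synthetic_observations.csv and
data/synthetic_truth.json, and data/observations_study.csv (the published
observation pool, which is printed in the assessment and safe to ship).
"""

from pathlib import Path

import numpy as np

from humpback_assess import (
    save_catch_series,
    save_observations,
    simulate_observations,
    true_trajectory,
)
from humpback_assess.scenarios import study_pool
from humpback_assess.synthetic import SyntheticTruth, generate_catches, truth_to_json

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "data"


def main() -> None:
    DATA.mkdir(exist_ok=True)
    truth = SyntheticTruth()
    catches = generate_catches(truth)
    traj = true_trajectory(truth, catches)
    rng = np.random.default_rng(truth.seed)
    data = simulate_observations(truth, traj, rng)

    save_catch_series(catches, DATA / "synthetic_catches.csv")
    save_observations(data.abundance_obs, data.growth_obs,
                      DATA / "synthetic_observations.csv")
    truth_to_json(truth, DATA / "synthetic_truth.json")

    pool = study_pool(catches)
    save_observations(pool.abundance_obs, pool.growth_obs,
                      DATA / "observations_study.csv")

    n_min_year = int(traj.years[traj.N.argmin()])
    print(f"truth: r_max={truth.r_max_true}, K={truth.K_true:.0f}")
    print(f"catches: {catches.start_year}-{catches.end_year}, "
          f"total {catches.total:.0f} whales, peak {catches.catches.max():.0f}")
    print(f"true trajectory: minimum {traj.N.min():.0f} whales in {n_min_year}; "
          f"N_2005={traj.population(2005):.0f}, N_2019={traj.population(2019):.0f}")
    print("observations drawn:")
    for ob in data.abundance_obs:
        print(f"  abundance {ob.year}: {ob.estimate:.0f} (CV {ob.cv})")
    for ob in data.growth_obs:
        print(f"  growth {ob.year_start}-{ob.year_end}: {ob.estimate:.4f} "
              f"(CV {ob.cv})")
    print(f"wrote 4 files to {DATA}")


if __name__ == "__main__":
    main()
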