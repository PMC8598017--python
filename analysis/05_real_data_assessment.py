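"""Assessment on the published catch series, when the user supplies it.

The "core hypothesis" whaling-removal series is published only as
supplementary R code alongside the original assessment and is not
redistributed with this project.  To reproduce the published posterior
summaries, export that supplementary code to plain text and either

* save the series as ``data/core_hypothesis_catches.csv`` (header
  ``year,catch``), or
* point this script at the R code file, from which the series is extracted:

    python analysis/05_real_data_assessment.py path/to/s1_code.R

With the series in place the script fits the Base Case and Updated models
(3 chains x 50,000 post-burn iterations, thin 50 — medians match the full
3 x 500,000 settings well inside MC error) against the published observation
pool and writes results/real_base_case_summary.csv and
results/real_updated_summary.csv.
"""

import sys
from dataclasses import replace
from pathlib import Path

from humpback_assess import MCMCConfig, PriorSpec, run_mcmc
from humpback_assess.io import extract_catch_series_from_r_code, load_catch_series
from humpback_assess.reporting import summarize
from humpback_assess.scenarios import build_scenario, study_pool

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
CATCHES_CSV = ROOT / "data" / "core_hypothesis_catches.csv"

REDUCED = MCMCConfig(n_burn=5_000, n_iter=50_000, thin=50, seed=17)


def main() -> None:
    if len(sys.argv) > 1:
        catches = extract_catch_series_from_r_code(sys.argv[1])
    elif CATCHES_CSV.exists():
        catches = load_catch_series(CATCHES_CSV)
    else:
        print(__doc__)
        print("no catch series found — nothing to do")
        return
    RESULTS.mkdir(exist_ok=True)
    pool = study_pool(catches)
    for i, name in enumerate(("base_case", "updated")):
        data, _ = build_scenario(name, pool)
        draws = run_mcmc(data, PriorSpec(), replace(REDUCED, seed=REDUCED.seed + i))
        tab = summarize(draws)
        tab.to_csv(RESULTS / f"real_{name}_summary.csv")
        print(f"\n{name} (R-hat max {max(draws.rhat.values()):.3f}):")
        print(tab.round(4).to_string())


if __name__ == "__main__":
    main()
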