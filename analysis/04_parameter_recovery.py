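"""Parameter-recovery experiment: does the pipeline find known truth?

Repeatedly draws observation sets from the synthetic ground truth at the
study's CVs, fits the model to each, and measures bias of the posterior
medians and coverage of the 95% equal-tailed intervals for r_max and K.
Each fit runs the study's three dispersed chains at reduced length (6,000
post-burn iterations per chain) — enough for stable medians and intervals
here, while keeping the safeguard against settling on a local posterior mode.

Writes results/recovery_replicates.csv and results/recovery_summary.csv.
"""

from pathlib import Path

import pandas as pd

from humpback_assess import MCMCConfig, PriorSpec
from humpback_assess.mcmc import tune_proposal
from humpback_assess.scenarios import build_scenario
from humpback_assess.synthetic import (
    SyntheticTruth,
    recovery_experiment,
    synthetic_pool,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

N_REPLICATES = 50


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    truth = SyntheticTruth()
    prior = PriorSpec()
    # tune once on a representative dataset, then freeze for all replicates
    data, _ = build_scenario("updated", synthetic_pool(truth))
    base_cfg = MCMCConfig(n_burn=1_000, n_iter=6_000, thin=6, n_chains=3, seed=3)
    cov = tune_proposal(base_cfg, data, prior)
    cfg = MCMCConfig(n_burn=1_000, n_iter=6_000, thin=6, n_chains=3,
                     proposal_cov=cov, seed=3)

    reps = recovery_experiment(truth, N_REPLICATES, cfg, prior=prior, seed=99)
    reps.to_csv(RESULTS / "recovery_replicates.csv", index=False)

    summary = pd.DataFrame(
        {
            "truth": [truth.r_max_true, truth.K_true],
            "mean_posterior_median": [reps.median_rmax.mean(), reps.median_K.mean()],
            "mean_bias": [reps.bias_rmax.mean(), reps.bias_K.mean()],
            "coverage_95": [reps.covered_rmax.mean(), reps.covered_K.mean()],
        },
        index=["r_max", "K"],
    )
    summary.index.name = "parameter"
    summary.to_csv(RESULTS / "recovery_summary.csv")

    print(f"{N_REPLICATES} replicates at the study observation CVs:")
    print(summary.round(4).to_string())
    print("95% interval coverage should sit near 0.95 "
          "(binomial band at n=50: roughly 0.86-1.0)")


if __name__ == "__main__":
    main()
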