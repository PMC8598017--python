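"""Derive the implied prior on carrying capacity by backward projection.

Uniform priors on N_2005 (500-22,000) and r_max (0-0.106), pushed through the
deterministic process model and the catch series, induce a prior on K.  This
script Monte-Carlo-samples that implied prior (10,000 draws, as in the
assessment) on the synthetic catch series and contrasts it with the flat
N_2005 prior: the catch history makes the K prior far more informative than
either marginal.

Writes results/implied_k_prior_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from humpback_assess import PriorSpec, implied_K_prior, load_catch_series

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    catches = load_catch_series(ROOT / "data" / "synthetic_catches.csv")
    spec = PriorSpec()
    rng = np.random.default_rng(2005)
    ks, fail = implied_K_prior(spec, catches, n=10_000, rng=rng)

    qs = np.quantile(ks, [0.025, 0.25, 0.5, 0.75, 0.975])
    summary = pd.DataFrame(
        {
            "n_draws": [10_000],
            "failure_fraction": [fail],
            "mean": [ks.mean()],
            "q2.5": [qs[0]], "q25": [qs[1]], "median": [qs[2]],
            "q75": [qs[3]], "q97.5": [qs[4]],
        }
    )
    summary.to_csv(RESULTS / "implied_k_prior_summary.csv", index=False)

    n_lo, n_hi = spec.n2005_bounds
    print(f"implied prior on K from {len(ks)} successful backprojections "
          f"({fail:.1%} failures):")
    print(f"  median {qs[2]:,.0f}, 95% interval {qs[0]:,.0f}-{qs[4]:,.0f}")
    print(f"  interquartile width {qs[3] - qs[1]:,.0f} whales, versus "
          f"{0.5 * (n_hi - n_lo):,.0f} for the flat N_2005 prior")
    print("the catch pulse shifts the whole K prior above the N_2005 bounds and "
          "couples K to r_max; how concentrated it is depends on the size of "
          "the removals (the historical series, with far larger early catches, "
          "induces a much tighter prior than this synthetic stand-in)")


if __name__ == "__main__":
    main()
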