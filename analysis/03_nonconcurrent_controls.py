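"""Impact of pooling non-concurrent control data for the added arm.

Runs the global-null scenario across the four variance scenarios and
both fixed cohort effects (tau = 0 and -0.5), comparing the concurrent
and pooled-control strategies for research comparison C.  The pattern of
interest: gross inflation of the type-I error whenever a random cohort
effect is present, damped inflation when a negative trend co-occurs, and
complete deflation (no rejections) under a pure negative trend.
Writes results/nonconcurrent_rates.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from platformsim import (
    build_design,
    make_scenario,
    mc_band,
    run_replications,
    summarize_rejections,
)

STRATEGIES = [
    "T-test C",
    "T-test C-nc",
    "Bonferroni",
    "Bonferroni-nc",
    "Dunnett.closed",
    "Dunnett.closed-nc",
]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--reps", type=int, default=2000)
    parser.add_argument("--seed", type=int, default=20240730)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    design = build_design("one")
    parts = []
    for vs in (1, 2, 3, 4):
        for tau in (0.0, -0.5):
            decisions, _, _ = run_replications(
                design,
                make_scenario("S0", vs, tau),
                args.reps,
                seed=args.seed,
                strategies=STRATEGIES,
                models=[],
            )
            summ = summarize_rejections(decisions)
            summ = summ[(summ.hypothesis == "any") | summ.strategy.str.startswith("T-test")]
            parts.append(summ.assign(variance_scenario=vs, tau=tau))
    table = pd.concat(parts, ignore_index=True)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "nonconcurrent_rates.csv", index=False)

    lo, hi = mc_band(0.05, args.reps)
    cnc = table[table.strategy == "T-test C-nc"]
    pivot = cnc.pivot_table(index="variance_scenario", columns="tau", values="rate")
    print("T-test C-nc rejection rate (rows: variance scenario, cols: tau):")
    print(pivot.to_string(float_format=lambda v: f"{v:.4f}"))
    print(
        f"\nMC band around 5%: [{lo:.4f}, {hi:.4f}].  With sigma_c = 0.38 "
        f"(scenarios 2 and 4) the pooled-control test is grossly inflated "
        f"at tau = 0; a negative trend damps that inflation, and with "
        f"sigma_c = 0 it removes rejections entirely."
    )


if __name__ == "__main__":
    main()
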