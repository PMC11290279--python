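"""Design-stage power of the per-comparison one-sided t-test.

Tabulates the exact noncentral-t power over per-arm sample sizes and
standardized effects, confirming that the study's per-arm size of 120
yields 90% power for an effect of 0.38 at one-sided alpha = 5%.
Writes results/design_power.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from platformsim import analytic_power


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    rows = [
        {"n_per_arm": n, "effect": d, "alpha": 0.05,
         "power": analytic_power(n, d, 0.05)}
        for n in (30, 60, 90, 120, 150)
        for d in (0.2, 0.38, 0.5)
    ]
    table = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "design_power.csv", index=False)

    headline = analytic_power(120, 0.38, 0.05)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(
        f"\nAt 120 subjects per arm the one-sided 5% t-test detects an "
        f"effect of 0.38 with power {headline:.3f} (the design target of 0.9)."
    )


if __name__ == "__main__":
    main()
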