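"""Compare one- vs two-learning-rate models by BIC across the cohort.

Fits both variants to every agent x condition and reports the fraction of
agents for whom the simpler one-rate model wins (ties included). With
48 trials per condition and one-rate generating agents, the one-rate model
should be preferred for a clear majority.

Inputs:  scratch/data/trials.csv (from 01)
Outputs: scratch/data/model_comparison.csv,
         results/model_comparison_fractions.csv
"""

import argparse
from pathlib import Path

import pandas as pd

import prosorl as P

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    data_dir = ROOT / "scratch" / "data"
    trials = P.read_trials_csv(data_dir / "trials.csv")

    report = P.compare_models(trials, seed=seed)
    report.to_csv(data_dir / "model_comparison.csv")

    fractions = pd.DataFrame(
        [
            {"condition": cond, "fraction_preferring_one_alpha": frac}
            for cond, frac in sorted(report.fraction_one_alpha.items())
        ]
    )
    fractions.to_csv(ROOT / "results" / "model_comparison_fractions.csv", index=False)
    print("fraction of agents preferring the one-learning-rate model (BIC):")
    print(fractions.round(3).to_string(index=False))
    mean_delta = report.per_fit.groupby("condition").delta_bic.mean()
    print("mean BIC(one) - BIC(two) per condition (negative favors one-rate):")
    print(mean_delta.round(2).to_string())


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=20)
    main(parser.parse_args().seed)
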