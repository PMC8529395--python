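"""Parameter recovery using the cohort's fitted parameters as ground truth.

Mirrors the validation design of the original study: take the 74 fitted
(alpha, beta) pairs per condition as generating parameters, simulate a
fresh dataset, refit it, and correlate true with recovered values per
condition. Also writes true-vs-recovered scatter plots.

Inputs:  scratch/data/fits_one_alpha.csv (from 02)
Outputs: results/recovery_metrics.csv, scratch/figures/recovery_*.png
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import prosorl as P

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    import pandas as pd

    fits = pd.read_csv(ROOT / "scratch" / "data" / "fits_one_alpha.csv")
    truth = fits[["agent_id", "condition", "alpha", "beta"]]

    report = P.run_recovery(truth, P.TaskConfig(), seed=seed)
    report.to_csv(ROOT / "results" / "recovery_metrics.csv")
    print(f"recovery over {report.n_agents} agents, 48 trials/condition:")
    print(
        report.metrics[
            ["condition", "parameter", "pearson_r", "spearman_rho", "bias", "rmse"]
        ]
        .round(3)
        .to_string(index=False)
    )

    fig_dir = ROOT / "scratch" / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    for param in ("alpha", "beta"):
        fig, axes = plt.subplots(1, 3, figsize=(11, 3.6), sharex=True, sharey=True)
        for ax, cond in zip(axes, P.Condition):
            sub = report.paired[report.paired.condition == cond.value]
            ax.scatter(sub[f"{param}_true"], sub[f"{param}_recovered"], s=12, alpha=0.7)
            lims = [sub[f"{param}_true"].min(), sub[f"{param}_true"].max()]
            ax.plot(lims, lims, "k--", lw=0.8)
            ax.set_title(cond.value)
            ax.set_xlabel(f"true {param}")
        axes[0].set_ylabel(f"recovered {param}")
        fig.tight_layout()
        fig.savefig(fig_dir / f"recovery_{param}.png", dpi=120)
        plt.close(fig)
    print(f"scatter plots in {fig_dir}")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=30)
    main(parser.parse_args().seed)
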