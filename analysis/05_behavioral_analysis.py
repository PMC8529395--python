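"""Behavioral statistics: learning curves, above-chance tests, age and
empathy correlations.

Reproduces the operational analyses on the synthetic cohort: per-condition
learning curves averaged across blocks, one-sample t-tests of performance
against chance (df = n - 1), age trends in fitted learning rates, and the
partial Spearman correlations linking cognitive empathy to Other-condition
learning beyond Self-condition learning (and age).

Inputs:  scratch/data/{trials,fits_one_alpha,agents}.csv (from 01-02)
Outputs: results/learning_curves.csv, results/above_chance.csv,
         results/correlations.csv, scratch/figures/learning_curves.png
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import prosorl as P

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    data_dir = ROOT / "scratch" / "data"
    trials = P.read_trials_csv(data_dir / "trials.csv")
    fits = pd.read_csv(data_dir / "fits_one_alpha.csv")
    res_dir = ROOT / "results"

    curves = P.learning_curves(trials)
    curves.to_csv(res_dir / "learning_curves.csv", index=False)

    perf = P.performance_summary(trials)
    rows = []
    for cond, sub in perf.groupby("condition"):
        res = P.above_chance_test(sub.fraction_correct)
        rows.append(
            {
                "condition": cond,
                "mean_fraction_correct": sub.fraction_correct.mean(),
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    above = pd.DataFrame(rows)
    above.to_csv(res_dir / "above_chance.csv", index=False)
    print("above-chance tests (vs 0.5):")
    print(above.round(4).to_string(index=False))

    # age trends in fitted learning rates, and empathy partial correlations
    wide = fits.pivot(index="agent_id", columns="condition", values="alpha")
    covars = perf.pivot(index="agent_id", columns="condition", values="fraction_correct")
    one = trials.drop_duplicates("agent_id").set_index("agent_id")[["age", "empathy"]]
    wide = wide.join(one).join(covars, rsuffix="_perf")
    rows = []
    for cond in ("self", "other", "no_one"):
        tr = P.age_trend(wide[cond], wide.age)
        rows.append(
            {
                "analysis": f"fitted_alpha_vs_age[{cond}]",
                "coefficient": tr.spearman_rho,
                "p": tr.spearman_p,
            }
        )
    rho, p = P.partial_spearman(wide.empathy, wide.other_perf, [wide.self_perf])
    rows.append({"analysis": "empathy_vs_other_performance|self_performance", "coefficient": rho, "p": p})
    rho, p = P.partial_spearman(wide.empathy, wide.other, [wide.self])
    rows.append({"analysis": "empathy_vs_other_alpha|self_alpha", "coefficient": rho, "p": p})
    rho, p = P.partial_spearman(wide.empathy, wide.other, [wide.self, wide.age])
    rows.append({"analysis": "empathy_vs_other_alpha|self_alpha,age", "coefficient": rho, "p": p})
    corr = pd.DataFrame(rows)
    corr.to_csv(res_dir / "correlations.csv", index=False)
    print("correlation analyses (Spearman / partial Spearman):")
    print(corr.round(3).to_string(index=False))

    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, sub in curves.groupby("condition"):
        ax.errorbar(
            sub.trial_in_block + 1, sub.fraction_correct, yerr=sub["sem"], label=cond
        )
    ax.axhline(0.5, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("trial within block")
    ax.set_ylabel("fraction high-contingency choice")
    ax.legend()
    fig.tight_layout()
    fig_dir = ROOT / "scratch" / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    fig.savefig(fig_dir / "learning_curves.png", dpi=120)
    plt.close(fig)


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=40)
    main(parser.parse_args().seed)
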