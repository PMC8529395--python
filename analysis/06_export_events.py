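"""Export neuroimaging-ready event files with model-derived modulators.

For each agent, replays the observed choice/outcome sequence under the
agent's own fitted per-condition parameters and writes one BIDS-style
events TSV per run: zero-duration decision events modulated by the chosen
expected value (EV), outcome events modulated by the prediction error
(PE), and missed trials as unmodulated rows.

Inputs:  scratch/data/{trials,fits_one_alpha}.csv (from 01-02)
Outputs: scratch/events/<agent>_run-<r>_events.tsv
"""

import argparse
from pathlib import Path

import pandas as pd

import prosorl as P

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    data_dir = ROOT / "scratch" / "data"
    trials = P.read_trials_csv(data_dir / "trials.csv")
    fits = pd.read_csv(data_dir / "fits_one_alpha.csv")

    out_dir = ROOT / "scratch" / "events"
    out_dir.mkdir(parents=True, exist_ok=True)
    n_files = 0
    for agent_id, sub in trials.groupby("agent_id"):
        events = P.events_from_fits(sub.reset_index(drop=True), fits)
        for run, run_events in events.groupby("run"):
            path = out_dir / f"{agent_id}_run-{run + 1}_events.tsv"
            P.write_events_tsv(run_events.drop(columns="run"), path)
            n_files += 1
    print(f"wrote {n_files} event files to {out_dir}")
    example = sorted(out_dir.glob("*_run-1_events.tsv"))[0]
    print(f"example ({example.name}):")
    print("\n".join(example.read_text().splitlines()[:5]))


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=50)
    main(parser.parse_args().seed)
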