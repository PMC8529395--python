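"""File I/O: tidy trial CSVs, YAML configs, and neuroimaging-ready event files.

Event files follow the BIDS events-TSV convention (onset and duration as
the first columns, tab-separated). Each non-missed trial contributes two
zero-duration events: a ``decision`` row whose parametric modulator is the
chosen expected value (EV) and an ``outcome`` row carrying the prediction
error (PE), both replayed under the agent's own fitted parameters. Missed
trials become a single ``missed`` row with no modulator, for use as a
regressor of no interest. Modulators are exported raw; within-run mean
centering is available behind a flag.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .model import RLParams, TRAJECTORY_COLUMNS, Variant, replay
from .task import Condition, TaskConfig, TRIAL_COLUMNS

__all__ = [
    "write_trials_csv",
    "read_trials_csv",
    "write_config_yaml",
    "read_config_yaml",
    "build_events",
    "events_from_fits",
    "write_events_tsv",
    "read_events_tsv",
    "EVENT_COLUMNS",
]


# ---------------------------------------------------------------------------
# Trial tables and configs


def write_trials_csv(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a tidy trial table (optionally with trajectory columns) to CSV."""
    table.to_csv(path, index=False)


def read_trials_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a trial CSV, restoring nullable choice/outcome dtypes."""
    frame = pd.read_csv(path)
    if "chosen_good" in frame.columns:
        frame["chosen_good"] = frame["chosen_good"].astype("boolean")
    if "outcome" in frame.columns:
        frame["outcome"] = frame["outcome"].astype("Int64")
    if "missed" in frame.columns:
        frame["missed"] = frame["missed"].astype(bool)
    return frame


def write_config_yaml(config: TaskConfig, path: Union[str, Path]) -> None:
    data = dataclasses.asdict(config)
    data["outcome_values"] = list(config.outcome_values)
    Path(path).write_text(yaml.safe_dump({"task": data}, sort_keys=False))


def read_config_yaml(path: Union[str, Path]) -> TaskConfig:
    data = yaml.safe_load(Path(path).read_text())["task"]
    data["outcome_values"] = tuple(data["outcome_values"])
    return TaskConfig(**data)


# ---------------------------------------------------------------------------
# Event files

EVENT_COLUMNS = ["onset", "duration", "trial_type", "condition", "run", "modulator", "value"]


def build_events(
    table: pd.DataFrame, mean_center: bool = False
) -> pd.DataFrame:
    """Build an event table from a trial table carrying trajectory columns.

    ``table`` must contain the trial columns plus ``chosen_q`` and ``pe``
    for every non-missed trial (a misalignment is a hard error). Decision
    rows are modulated by EV (the chosen expected value), outcome rows by
    PE; both have zero duration. Rows are sorted by run and onset.
    """
    for col in ("chosen_q", "pe"):
        if col not in table.columns:
            raise ValueError(f"trial table lacks trajectory column {col!r}")
    playable = table[~table["missed"].astype(bool)]
    if playable[["chosen_q", "pe"]].isna().any().any():
        raise ValueError("trajectory misaligned: non-missed trial without chosen_q/pe")

    records = []
    for rec in table.to_dict("records"):
        base = {"condition": rec["condition"], "run": int(rec["run"])}
        if bool(rec["missed"]):
            records.append(
                {
                    "onset": float(rec["onset_choice_s"]),
                    "duration": 0.0,
                    "trial_type": "missed",
                    "modulator": "",
                    "value": np.nan,
                    **base,
                }
            )
            continue
        records.append(
            {
                "onset": float(rec["onset_choice_s"]),
                "duration": 0.0,
                "trial_type": "decision",
                "modulator": "EV",
                "value": float(rec["chosen_q"]),
                **base,
            }
        )
        records.append(
            {
                "onset": float(rec["onset_outcome_s"]),
                "duration": 0.0,
                "trial_type": "outcome",
                "modulator": "PE",
                "value": float(rec["pe"]),
                **base,
            }
        )
    events = pd.DataFrame.from_records(records, columns=EVENT_COLUMNS)
    events = events.sort_values(["run", "onset"], kind="stable").reset_index(drop=True)
    if mean_center:
        for (run, mod), idx in events.groupby(["run", "modulator"]).groups.items():
            if mod:
                events.loc[idx, "value"] -= events.loc[idx, "value"].mean()
    return events


def events_from_fits(
    table: pd.DataFrame,
    fits: Union[pd.DataFrame, Mapping[Condition, RLParams]],
    q0: float = 0.0,
    outcome_values: tuple[int, int] = (1, -1),
    mean_center: bool = False,
) -> pd.DataFrame:
    """Event table for one agent, replaying their own fitted parameters.

    ``fits`` is either a mapping condition -> RLParams or a fit table with
    agent_id/condition/alpha/beta columns restricted to this agent. The
    observed choice/outcome sequence of each condition is replayed under
    that condition's parameters to obtain the EV and PE modulators.
    """
    if isinstance(fits, pd.DataFrame):
        if table["agent_id"].nunique() != 1:
            raise ValueError("events_from_fits expects a single agent's trials")
        agent = table["agent_id"].iloc[0]
        sub = fits[fits["agent_id"] == agent]
        params = {}
        for rec in sub.to_dict("records"):
            variant = Variant(rec.get("variant", Variant.ONE_ALPHA.value))
            if variant is Variant.ONE_ALPHA:
                params[Condition(rec["condition"])] = RLParams.one(
                    float(rec["alpha"]), float(rec["beta"])
                )
            else:
                params[Condition(rec["condition"])] = RLParams.two(
                    float(rec["alpha_gain"]), float(rec["alpha_loss"]), float(rec["beta"])
                )
    else:
        params = dict(fits)

    enriched = table.copy()
    for col in TRAJECTORY_COLUMNS:
        enriched[col] = np.nan
    for cond, p in params.items():
        mask = enriched["condition"] == cond.value
        traj = replay(enriched[mask], p, q0=q0, outcome_values=outcome_values)
        enriched.loc[traj.index, TRAJECTORY_COLUMNS] = traj[TRAJECTORY_COLUMNS].to_numpy()
    present = set(enriched.loc[~enriched["missed"].astype(bool), "condition"])
    missing = present - {c.value for c in params}
    if missing:
        raise ValueError(f"no fitted parameters for conditions: {sorted(missing)}")
    return build_events(enriched, mean_center=mean_center)


def write_events_tsv(events: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a BIDS-style events TSV (onsets with 4 decimal places)."""
    out = events.copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.4f", na_rep="n/a")


def read_events_tsv(path: Union[str, Path]) -> pd.DataFrame:
    """Read an events TSV written by :func:`write_events_tsv`."""
    frame = pd.read_csv(path, sep="\t", na_values=["n/a"], keep_default_na=True)
    if "modulator" in frame.columns:
        frame["modulator"] = frame["modulator"].fillna("")
    return frame
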