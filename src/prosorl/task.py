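"""Structure and reward schedule of the three-beneficiary probabilistic learning task.

Participants repeatedly choose between two pictures; one carries a high
probability of winning a point, the other a high probability of losing one.
Blocks are played for one of three beneficiaries (Self, an unknown Other, or
No One), each block starting with a fresh picture pair so the contingencies
must be relearned. Points in the paid conditions convert to money with a
floor and a ceiling.

This module encodes that design as data (`TaskConfig`, `Trial`) plus a
seeded session generator, the per-trial outcome sampler, and the
points-to-money conversion.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "TaskConfig",
    "Trial",
    "generate_session",
    "sample_outcome",
    "payout",
    "session_to_frame",
    "frame_to_trials",
    "TRIAL_COLUMNS",
]


class Condition(enum.Enum):
    """Beneficiary of a block's outcomes."""

    SELF = "self"
    OTHER = "other"
    NO_ONE = "no_one"

    def __str__(self) -> str:  # tidy-table friendly
        return self.value


@dataclass(frozen=True)
class TaskConfig:
    """Full specification of task structure and reinforcement contingencies.

    Defaults reproduce the original design: 3 runs, one 16-trial block per
    condition per run (144 trials, 48 per condition), 75/25 reward
    contingencies with +1/-1 point outcomes, and a 0.25 EUR/point conversion
    clamped to [1, 12] EUR.
    """

    n_runs: int = 3
    blocks_per_condition_per_run: int = 1
    trials_per_block: int = 16
    p_reward_good: float = 0.75
    outcome_values: tuple[int, int] = (1, -1)  # (reward, punishment)
    point_value_eur: float = 0.25
    payout_floor_eur: float = 1.0
    payout_ceiling_eur: float = 12.0
    response_window_ms: float = 2500.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_runs", "blocks_per_condition_per_run", "trials_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count, got {getattr(self, name)}")
        if not 0.5 < self.p_reward_good <= 1.0:
            raise ValueError(
                f"p_reward_good must lie in (0.5, 1], got {self.p_reward_good}"
            )
        reward, punishment = self.outcome_values
        if reward <= punishment:
            raise ValueError("outcome_values must be (reward, punishment) with reward > punishment")
        if self.payout_floor_eur > self.payout_ceiling_eur:
            raise ValueError("payout floor exceeds ceiling")
        if self.response_window_ms <= 0:
            raise ValueError("response_window_ms must be positive")

    @property
    def n_trials_total(self) -> int:
        return self.n_runs * len(Condition) * self.blocks_per_condition_per_run * self.trials_per_block

    @property
    def n_trials_per_condition(self) -> int:
        return self.n_runs * self.blocks_per_condition_per_run * self.trials_per_block


@dataclass(frozen=True)
class Trial:
    """One decision of one agent.

    Missed ("Too late") trials carry no choice and no outcome; they are
    excluded from value updating and analyses. ``chosen_good`` is True when
    the high-reward-contingency picture was selected.
    """

    agent_id: str
    run: int
    block: int  # block index within run
    condition: Condition
    trial_in_block: int
    pair_id: str  # picture pair; fresh per block, unique across blocks
    chosen_good: Optional[bool] = None
    outcome: Optional[int] = None
    missed: bool = False
    onset_choice_s: float = np.nan
    onset_outcome_s: float = np.nan

    def __post_init__(self) -> None:
        if self.missed and (self.chosen_good is not None or self.outcome is not None):
            raise ValueError("missed trials carry no choice and no outcome")


TRIAL_COLUMNS = [
    "agent_id",
    "run",
    "block",
    "condition",
    "trial_in_block",
    "pair_id",
    "chosen_good",
    "outcome",
    "missed",
    "onset_choice_s",
    "onset_outcome_s",
]

# Onset timing constants (seconds), used only to make event-file export
# realistic; they have no effect on modeling.
_INSTRUCTION_S = 2.0
_FRAME_EXTRA_S = 0.5
_PRE_OUTCOME_JITTER_S = (1.0, 2.0)
_OUTCOME_S = 1.0
_ITI_JITTER_S = (1.0, 8.0)


def _latin_rows(rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded 3x3 Latin square over condition indices: cyclic shifts of a
    random permutation, with the row order shuffled."""
    base = rng.permutation(len(Condition))
    rows = [np.roll(base, k) for k in range(len(Condition))]
    order = rng.permutation(len(rows))
    return [rows[i] for i in order]


def generate_session(
    config: TaskConfig, seed: int, agent_id: str = "agent-000"
) -> list[Trial]:
    """Generate the ordered trial skeleton of one session (no choices yet).

    Each run contains ``blocks_per_condition_per_run`` blocks per condition;
    condition order within runs follows a seeded Latin-square assignment
    (runs beyond three cycle through the square). Every block gets a fresh
    ``pair_id``. Onset times accumulate within a run with uniform jitters.
    """
    rng = np.random.default_rng(seed)
    conditions = list(Condition)
    rows = _latin_rows(rng)

    trials: list[Trial] = []
    pair_counter = 0
    for run in range(config.n_runs):
        row = rows[run % len(rows)]
        t = 0.0
        block_in_run = 0
        for _rep in range(config.blocks_per_condition_per_run):
            for cond_idx in row:
                condition = conditions[int(cond_idx)]
                pair_id = f"pair{pair_counter:04d}"
                pair_counter += 1
                t += _INSTRUCTION_S
                for k in range(config.trials_per_block):
                    onset_choice = t
                    onset_outcome = (
                        onset_choice
                        + config.response_window_ms / 1000.0
                        + _FRAME_EXTRA_S
                        + rng.uniform(*_PRE_OUTCOME_JITTER_S)
                    )
                    t = onset_outcome + _OUTCOME_S + rng.uniform(*_ITI_JITTER_S)
                    trials.append(
                        Trial(
                            agent_id=agent_id,
                            run=run,
                            block=block_in_run,
                            condition=condition,
                            trial_in_block=k,
                            pair_id=pair_id,
                            onset_choice_s=onset_choice,
                            onset_outcome_s=onset_outcome,
                        )
                    )
                block_in_run += 1
    return trials


def sample_outcome(
    chosen_good: bool, config: TaskConfig, rng: np.random.Generator
) -> int:
    """Draw the point outcome of a non-missed choice.

    The good stimulus rewards with probability ``p_reward_good``; the bad
    stimulus with ``1 - p_reward_good``. Draws are i.i.d. across trials.
    """
    reward, punishment = config.outcome_values
    p = config.p_reward_good if chosen_good else 1.0 - config.p_reward_good
    return reward if rng.random() < p else punishment


def payout(total_points: int, config: TaskConfig) -> float:
    """Convert a net point total to money: clamp(value * points, floor, ceiling)."""
    raw = config.point_value_eur * total_points
    return float(min(max(raw, config.payout_floor_eur), config.payout_ceiling_eur))


def session_to_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    """Tidy one-row-per-trial table (columns as in :data:`TRIAL_COLUMNS`)."""
    records = []
    for t in trials:
        rec = dataclasses.asdict(t)
        rec["condition"] = t.condition.value
        records.append(rec)
    frame = pd.DataFrame.from_records(records, columns=TRIAL_COLUMNS)
    frame["chosen_good"] = frame["chosen_good"].astype("boolean")
    frame["outcome"] = frame["outcome"].astype("Int64")
    frame["missed"] = frame["missed"].astype(bool)
    return frame


def frame_to_trials(frame: pd.DataFrame) -> list[Trial]:
    """Inverse of :func:`session_to_frame`."""
    trials = []
    for rec in frame.to_dict("records"):
        chosen = rec["chosen_good"]
        outcome = rec["outcome"]
        trials.append(
            Trial(
                agent_id=str(rec["agent_id"]),
                run=int(rec["run"]),
                block=int(rec["block"]),
                condition=Condition(rec["condition"]),
                trial_in_block=int(rec["trial_in_block"]),
                pair_id=str(rec["pair_id"]),
                chosen_good=None if pd.isna(chosen) else bool(chosen),
                outcome=None if pd.isna(outcome) else int(outcome),
                missed=bool(rec["missed"]),
                onset_choice_s=float(rec["onset_choice_s"]),
                onset_outcome_s=float(rec["onset_outcome_s"]),
            )
        )
    return trials
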