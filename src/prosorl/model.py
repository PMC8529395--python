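"""Rescorla-Wagner value learning with softmax choice.

The learner tracks an expected value Q for each of the two pictures in the
current block. After each outcome R the chosen picture's value moves a
fraction alpha toward it::

    Q <- Q + alpha * (R - Q)

where ``R - Q`` is the prediction error. Choices follow a softmax on the two
Q values with inverse temperature beta (beta = 0 is random choice; the sign
of beta is unconstrained). A two-learning-rate variant applies separate
alphas after reward and punishment outcomes, gated on outcome valence.

Values reset to ``q0`` at every block start (each block introduces a new
picture pair) and never transfer between conditions; the unchosen picture is
never updated.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .task import Condition, TaskConfig, Trial, sample_outcome, session_to_frame

__all__ = [
    "Variant",
    "RLParams",
    "rw_update",
    "effective_alpha",
    "softmax_prob",
    "SimulationResult",
    "simulate_choices",
    "replay",
    "TRAJECTORY_COLUMNS",
]


class Variant(enum.Enum):
    ONE_ALPHA = "one_alpha"
    TWO_ALPHA = "two_alpha"


@dataclass(frozen=True)
class RLParams:
    """Learning-rate / inverse-temperature parameter set for one condition.

    ``ONE_ALPHA`` uses ``alpha``; ``TWO_ALPHA`` uses ``alpha_gain`` and
    ``alpha_loss``. Rates must lie strictly inside (0, 1); beta may be any
    finite real, negative included.
    """

    variant: Variant
    beta: float
    alpha: Optional[float] = None
    alpha_gain: Optional[float] = None
    alpha_loss: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if self.variant is Variant.ONE_ALPHA:
            if self.alpha is None:
                raise ValueError("ONE_ALPHA requires alpha")
            rates = {"alpha": self.alpha}
        else:
            if self.alpha_gain is None or self.alpha_loss is None:
                raise ValueError("TWO_ALPHA requires alpha_gain and alpha_loss")
            rates = {"alpha_gain": self.alpha_gain, "alpha_loss": self.alpha_loss}
        for name, rate in rates.items():
            if not 0.0 < rate < 1.0:
                raise ValueError(f"{name} must lie strictly inside (0, 1), got {rate}")

    @classmethod
    def one(cls, alpha: float, beta: float) -> "RLParams":
        return cls(variant=Variant.ONE_ALPHA, beta=beta, alpha=alpha)

    @classmethod
    def two(cls, alpha_gain: float, alpha_loss: float, beta: float) -> "RLParams":
        return cls(
            variant=Variant.TWO_ALPHA,
            beta=beta,
            alpha_gain=alpha_gain,
            alpha_loss=alpha_loss,
        )

    @property
    def rates(self) -> tuple[float, float]:
        """(gain rate, loss rate); identical for the one-rate variant."""
        if self.variant is Variant.ONE_ALPHA:
            return (self.alpha, self.alpha)  # type: ignore[return-value]
        return (self.alpha_gain, self.alpha_loss)  # type: ignore[return-value]


def rw_update(q_chosen: float, outcome: float, alpha: float) -> float:
    """Delta-rule update of the chosen option's value: q + alpha*(R - q)."""
    return q_chosen + alpha * (outcome - q_chosen)


def effective_alpha(
    outcome: float, params: RLParams, outcome_values: tuple[int, int] = (1, -1)
) -> float:
    """Learning rate applied after ``outcome``.

    The two-rate variant gates on outcome valence: the gain rate after the
    reward value, the loss rate after the punishment value.
    """
    reward, punishment = outcome_values
    if outcome not in (reward, punishment):
        raise ValueError(f"outcome {outcome} not in outcome_values {outcome_values}")
    gain, loss = params.rates
    return gain if outcome == reward else loss


def softmax_prob(q_pair: Sequence[float], beta: float) -> np.ndarray:
    """Softmax choice probabilities exp(beta*q_i) / sum_j exp(beta*q_j).

    Overflow-safe via max-shifting; beta = 0 yields the uniform distribution.
    """
    z = beta * np.asarray(q_pair, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite beta * q")
    z -= z.max()
    ez = np.exp(z)
    return ez / ez.sum()


TRAJECTORY_COLUMNS = ["chosen_q", "pe", "choice_prob"]


@dataclass
class SimulationResult:
    """Completed trials plus the model trajectory that generated them.

    ``trials`` carries choices and outcomes; ``trajectory`` has one row per
    non-missed trial with the pre-outcome chosen value (``chosen_q``), the
    prediction error (``pe = outcome - chosen_q``), and the probability of
    the made choice.
    """

    trials: list[Trial]
    trajectory: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Tidy trial table with trajectory columns joined (NaN on misses)."""
        frame = session_to_frame(self.trials)
        for col in TRAJECTORY_COLUMNS:
            frame[col] = np.nan
        if len(self.trajectory):
            frame.loc[self.trajectory.index, TRAJECTORY_COLUMNS] = self.trajectory[
                TRAJECTORY_COLUMNS
            ].to_numpy()
        return frame


def _params_by_condition(
    params: Union[RLParams, Mapping[Condition, RLParams]],
    conditions: set[Condition],
) -> dict[Condition, RLParams]:
    if isinstance(params, RLParams):
        return {c: params for c in conditions}
    missing = conditions - set(params)
    if missing:
        raise ValueError(f"missing RLParams for conditions: {sorted(c.value for c in missing)}")
    return dict(params)


def simulate_choices(
    session: Sequence[Trial],
    params: Union[RLParams, Mapping[Condition, RLParams]],
    config: TaskConfig,
    seed: int,
    q0: float = 0.0,
    miss_prob: float = 0.0,
) -> SimulationResult:
    """Play one session with a softmax Rescorla-Wagner agent.

    Values reset to ``q0`` for both pictures at every block start. On each
    non-missed trial the choice is sampled from the softmax over the current
    pair values, the outcome from the task contingencies, and the chosen
    value is updated with the valence-appropriate learning rate. Identical
    seeds give identical output.
    """
    if not 0.0 <= miss_prob < 1.0:
        raise ValueError("miss_prob must lie in [0, 1)")
    by_cond = _params_by_condition(params, {t.condition for t in session})
    rng = np.random.default_rng(seed)

    out_trials: list[Trial] = []
    traj_records: list[dict] = []
    current_pair: Optional[str] = None
    q = np.array([q0, q0])  # index 0 = bad picture, 1 = good picture

    for i, skel in enumerate(session):
        if skel.pair_id != current_pair:
            current_pair = skel.pair_id
            q = np.array([q0, q0])
        if miss_prob > 0.0 and rng.random() < miss_prob:
            out_trials.append(
                dataclasses.replace(skel, chosen_good=None, outcome=None, missed=True)
            )
            continue
        p = by_cond[skel.condition]
        probs = softmax_prob(q, p.beta)
        chosen = int(rng.random() < probs[1])  # 1 = good picture
        chosen_q = float(q[chosen])
        outcome = sample_outcome(bool(chosen), config, rng)
        pe = outcome - chosen_q
        q[chosen] = rw_update(chosen_q, outcome, effective_alpha(outcome, p, config.outcome_values))
        out_trials.append(
            dataclasses.replace(skel, chosen_good=bool(chosen), outcome=outcome, missed=False)
        )
        traj_records.append(
            {
                "index": i,
                "chosen_q": chosen_q,
                "pe": pe,
                "choice_prob": float(probs[chosen]),
            }
        )

    trajectory = pd.DataFrame.from_records(
        traj_records, columns=["index"] + TRAJECTORY_COLUMNS
    ).set_index("index")
    trajectory.index.name = None
    return SimulationResult(trials=out_trials, trajectory=trajectory)


def replay(
    trials: Union[Sequence[Trial], pd.DataFrame],
    params: RLParams,
    q0: float = 0.0,
    outcome_values: tuple[int, int] = (1, -1),
) -> pd.DataFrame:
    """Replay observed choices/outcomes under fixed parameters.

    Returns one row per non-missed trial with ``chosen_q``, ``pe`` and
    ``choice_prob``, preserving the input order and resetting values at every
    ``pair_id`` change. This is the reference trajectory used both for
    likelihood evaluation and for building parametric-modulator event files
    from an agent's own fitted parameters.
    """
    if isinstance(trials, pd.DataFrame):
        rows = trials.to_dict("records")
        index = list(trials.index)
    else:
        rows = []
        index = []
        for i, t in enumerate(trials):
            rows.append(
                {
                    "pair_id": t.pair_id,
                    "chosen_good": t.chosen_good,
                    "outcome": t.outcome,
                    "missed": t.missed,
                }
            )
            index.append(i)

    records = []
    current_pair: Optional[str] = None
    q = np.array([q0, q0])
    for idx, rec in zip(index, rows):
        if rec["pair_id"] != current_pair:
            current_pair = rec["pair_id"]
            q = np.array([q0, q0])
        if bool(rec["missed"]):
            continue
        chosen = int(bool(rec["chosen_good"]))
        outcome = float(rec["outcome"])
        probs = softmax_prob(q, params.beta)
        chosen_q = float(q[chosen])
        pe = outcome - chosen_q
        q[chosen] = rw_update(
            chosen_q, outcome, effective_alpha(outcome, params, outcome_values)
        )
        records.append(
            {
                "index": idx,
                "chosen_q": chosen_q,
                "pe": pe,
                "choice_prob": float(probs[chosen]),
            }
        )
    out = pd.DataFrame.from_records(records, columns=["index"] + TRAJECTORY_COLUMNS)
    out = out.set_index("index")
    out.index.name = None
    return out
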