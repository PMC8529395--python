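import numpy as np
import pandas as pd
import pytest

import prosorl as P


@pytest.fixture(scope="session")
def config():
    return P.TaskConfig()


@pytest.fixture(scope="session")
def session_trials(config):
    return P.generate_session(config, seed=11)


@pytest.fixture(scope="session")
def learner_frame(config, session_trials):
    """One simulated session of a moderately strong one-rate learner."""
    params = P.RLParams.one(alpha=0.3, beta=5.0)
    return P.simulate_choices(session_trials, params, config, seed=21).to_frame()


@pytest.fixture(scope="session")
def hand_sequence():
    """Three-trial single-block choice sequence for hand-replay oracles.

    With q0 = 0, alpha = 0.3, beta = 2: choices good/good/bad with outcomes
    +1/-1/+1 give choice probabilities 0.5, 1/(1+e^-0.6), 1 - 1/(1+e^0.18)
    and chosen values 0, 0.3, 0 (the bad option is untouched).
    """
    rows = []
    for k, (chosen, outcome) in enumerate([(True, 1), (True, -1), (False, 1)]):
        rows.append(
            {
                "agent_id": "a0",
                "run": 0,
                "block": 0,
                "condition": "self",
                "trial_in_block": k,
                "pair_id": "pair0000",
                "chosen_good": chosen,
                "outcome": outcome,
                "missed": False,
                "onset_choice_s": float(10 * k),
                "onset_outcome_s": float(10 * k + 4),
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort_table(config):
    """Simulated trials of a small default-spec cohort (8 agents)."""
    spec = P.CohortSpec(n_agents=8, seed=5)
    agents = P.generate_cohort(spec)
    return P.simulate_cohort(agents, config, seed=6)
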