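import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dynaprl import task

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


def random_session(rng, n=10):
    """Random binary choice/reward arrays (no model structure)."""
    return (rng.integers(0, 2, n).astype(np.int8),
            rng.integers(0, 2, n).astype(np.int8))


def make_trials(choices, rewards, rat="r0", session="s0", contrast="HC",
                better="left", block_ordinal=1):
    """Hand-build a minimal trial table from choice/reward sequences."""
    n = len(choices)
    return pd.DataFrame({
        "rat_id": rat, "session_id": session,
        "trial_index": np.arange(1, n + 1),
        "block_ordinal": block_ordinal,
        "block_trial": np.arange(1, n + 1),
        "contrast_label": contrast,
        "choice": choices, "reward": rewards,
        "reward_volume": [33.0 if r else 0.0 for r in rewards],
        "valid": True, "better_side": better,
    })


@pytest.fixture(scope="session")
def reference_cohort():
    """Small two-group cohort from the package's reference asymmetric-agent
    distributions; shared across tests that only read it."""
    cfg = task.CohortConfig(
        group_labels=("group1", "group2"), n_rats_per_group=3,
        sessions_per_rat=2, trials_per_session=300,
        generating_model="asym",
        group_param_distributions=task.REFERENCE_GROUP_PARAMS,
        seed=1)
    trials, true_params = task.generate_cohort(cfg)
    return trials, true_params


@pytest.fixture(scope="session")
def agent_session():
    """One moderately long standard-agent session with its latent trace."""
    trials, trace = task.simulate_session(
        "standard", {"alpha": 0.4, "beta": 3.0},
        task.TaskConfig(n_trials=500), seed=11)
    return trials, trace
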