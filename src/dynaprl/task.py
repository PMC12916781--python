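"""Simulator for the dynamic probabilistic reversal-learning (dynaPRL) task.

The task is a two-lever bandit whose reward contingencies reverse in blocks.
Three block types differ in the contrast between the two levers' reward
probabilities:

* ``HC`` (high contrast): 0.8 vs 0.1
* ``LC`` (low contrast):  0.6 vs 0.3
* ``NC`` (no contrast):   0.45 vs 0.45

Blocks last 15-30 trials (length drawn uniformly).  Block transitions follow
two rules: a no-contrast block is never immediately repeated, and the side of
the higher-probability lever alternates between consecutive contrast blocks.
In contrast blocks, a scheduled transition is deferred while the animal's
last four or more choices were all of the low-probability lever, so that
reversals do not land mid-confusion.  After the twelfth trial of a contrast
block, each rewarded trial independently receives a reward-magnitude
manipulation with probability 0.40 (half of those halve the ~33 uL drop to
16.5 uL, half double it to 66 uL); models consume reward as binary 0/1
regardless of volume.

Simulated choices come from an RL agent (any model in
:mod:`dynaprl.models`), or from the special policies ``"oracle"`` (always
the better lever; random in NC blocks) and ``"random"`` (uniform).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import models as _m
from .models import ACTIONS, get_model, make_params, session_negloglik

CONTRAST_PROBS: dict[str, tuple[float, float]] = {
    "HC": (0.8, 0.1),
    "LC": (0.6, 0.3),
    "NC": (0.45, 0.45),
}
CONTRAST_LABELS = ("HC", "LC", "NC")
BLOCK_LEN_RANGE = (15, 30)
REWARD_UL = 33.0
REWARD_HALF_UL = 16.5
REWARD_DOUBLE_UL = 66.0
MAGNITUDE_PROB = 0.40
MAGNITUDE_MIN_TRIAL = 12  # manipulation only after this many block trials
DEFER_STREAK = 4

TRIAL_COLUMNS = ("rat_id", "session_id", "trial_index", "block_ordinal",
                 "block_trial", "contrast_label", "choice", "reward",
                 "reward_volume", "valid")

POLICY_AGENTS = ("oracle", "random")

# Reference generating distributions for the asymmetric model, (loc, scale)
# of a bounds-truncated normal per parameter.  Calibrated once so that
# simulated cohorts reproduce the task's qualitative signatures: empirical
# reward rate ordered HC > LC > NC, reversal adaptation within ~6 trials,
# and win-stay far above lose-shift.  group1 carries the win-biased
# asymmetry (higher learning rates, stronger value decay after losses);
# group2 the more loss-protective profile.
REFERENCE_GROUP_PARAMS: dict[str, dict[str, tuple]] = {
    "group1": {"alpha_pos": (0.65, 0.06), "alpha_neg": (0.55, 0.07),
               "gamma_pos": (0.96, 0.015), "gamma_neg": (0.93, 0.02),
               "beta": (5.0, 0.6)},
    "group2": {"alpha_pos": (0.50, 0.06), "alpha_neg": (0.45, 0.07),
               "gamma_pos": (0.96, 0.015), "gamma_neg": (0.965, 0.012),
               "beta": (5.0, 0.6)},
}


@dataclass(frozen=True)
class BlockSpec:
    """One block of the task schedule."""

    contrast_label: str
    p_reward_left: float
    p_reward_right: float
    planned_length: int
    better_side: str | None  # "left", "right" or None for NC

    def __post_init__(self) -> None:
        if self.contrast_label not in CONTRAST_LABELS:
            raise ValueError(f"unknown contrast {self.contrast_label!r}")
        pair = frozenset(CONTRAST_PROBS[self.contrast_label])
        if frozenset((self.p_reward_left, self.p_reward_right)) != pair:
            raise ValueError("reward probabilities do not match contrast label")
        if not BLOCK_LEN_RANGE[0] <= self.planned_length <= BLOCK_LEN_RANGE[1]:
            raise ValueError("planned_length outside 15-30")
        if (self.better_side is None) != (self.contrast_label == "NC"):
            raise ValueError("better_side must be None exactly for NC blocks")


@dataclass(frozen=True)
class TaskConfig:
    """Session-level simulation settings."""

    n_trials: int = 500
    invalid_rate: float = 0.0
    magnitude_manipulation: bool = True
    defer_on_incorrect_streak: bool = True

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 <= self.invalid_rate < 1.0:
            raise ValueError("invalid_rate must be in [0, 1)")


class _AgentState:
    """Incremental agent: softmax policy plus the model's update rule."""

    def __init__(self, model: str, params) -> None:
        self.model = model
        self.params = params
        self.v = np.zeros(2)
        self.avg_rpe = 0.0
        self.rtrace = 0.0
        self.prev_reward = 0
        self.prev_choice: int | None = None
        self.first_trial = True

    def choice_probs(self) -> np.ndarray:
        p = self.params
        if self.model == "asym_ch" and self.prev_choice is not None:
            z = p.beta * self.v.copy()
            z[self.prev_choice] += p.phi
            z -= z.max()
            e = np.exp(z)
            return e / e.sum()
        return _m.softmax_prob(self.v, p.beta)

    def update(self, choice: int, reward: int) -> None:
        p = self.params
        if self.model == "standard":
            self.v, _ = _m.step_standard(self.v, choice, reward, p)
        elif self.model == "avg_rpe":
            self.v, _, self.avg_rpe = _m.step_avg_rpe(
                self.v, self.avg_rpe, choice, reward, p)
        elif self.model == "grs":
            prev_r = 0 if self.first_trial else self.prev_reward
            if self.first_trial:
                # Rtrace stays at its initial 0 on the first trial
                rpe = reward + p.w_r * self.rtrace - self.v[choice]
                self.v = self.v.copy()
                self.v[choice] += p.alpha * rpe
            else:
                self.v, _, self.rtrace = _m.step_grs(
                    self.v, self.rtrace, choice, reward, prev_r, p)
        else:  # asym / asym_ch
            self.v, _ = _m.step_asymmetric(self.v, choice, reward, p)
        self.prev_reward = reward
        self.prev_choice = choice
        self.first_trial = False


def _draw_block(rng: np.random.Generator, prev_contrast: str | None,
                last_better: int | None) -> tuple[str, int | None, int]:
    """Draw the next block's (contrast, better side index, planned length)."""
    options = [c for c in CONTRAST_LABELS
               if not (c == "NC" and prev_contrast == "NC")]
    contrast = options[rng.integers(len(options))]
    if contrast == "NC":
        better = None
    elif last_better is None:
        better = int(rng.integers(2))
    else:
        better = 1 - last_better
    length = int(rng.integers(BLOCK_LEN_RANGE[0], BLOCK_LEN_RANGE[1] + 1))
    return contrast, better, length


def simulate_session(model: str, params, config: TaskConfig | None = None,
                     seed: int | None = None, rat_id: str = "rat0",
                     session_id: str = "s0"):
    """Simulate one dynaPRL session for an agent.

    Parameters
    ----------
    model:
        A model identifier from :mod:`dynaprl.models`, or ``"oracle"`` /
        ``"random"`` for the fixed reference policies.
    params:
        Model parameters (mapping, sequence or dataclass); ignored for the
        reference policies.
    config:
        :class:`TaskConfig`; defaults to 500 trials, no invalid trials.
    seed:
        Seed for all randomness in the session.

    Returns
    -------
    (trials, trace):
        ``trials`` is a DataFrame with the canonical trial columns;
        ``trace`` is the agent's latent trace (per-trial values, RPE,
        auxiliary trace and choice probability) obtained by replaying the
        generated choices through the model, or ``None`` for the reference
        policies.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    is_policy = model in POLICY_AGENTS
    if not is_policy:
        spec = get_model(model)
        if not isinstance(params, spec.param_cls):
            params = make_params(model, params)
        agent = _AgentState(model, params)

    contrast, better, length = _draw_block(rng, None, None)
    # NC blocks need a seeded "correct" side for perseveration scoring only;
    # reward probabilities are symmetric there.
    block_ordinal = 1
    block_trial = 0
    consec_incorrect = 0
    last_better = better

    rows = []
    for trial_index in range(1, config.n_trials + 1):
        block_trial += 1
        if contrast == "NC":
            p_left = p_right = CONTRAST_PROBS["NC"][0]
        else:
            hi, lo = CONTRAST_PROBS[contrast]
            p_left, p_right = (hi, lo) if better == 0 else (lo, hi)

        if is_policy:
            if model == "random" or better is None:
                choice = int(rng.integers(2))
            else:
                choice = better
        else:
            probs = agent.choice_probs()
            choice = int(rng.random() < probs[1])

        valid = not (config.invalid_rate > 0
                     and rng.random() < config.invalid_rate)
        if valid:
            p_rew = p_left if choice == 0 else p_right
            reward = int(rng.random() < p_rew)
            volume = 0.0
            if reward:
                volume = REWARD_UL
                if (config.magnitude_manipulation and contrast != "NC"
                        and block_trial > MAGNITUDE_MIN_TRIAL
                        and rng.random() < MAGNITUDE_PROB):
                    volume = (REWARD_HALF_UL if rng.random() < 0.5
                              else REWARD_DOUBLE_UL)
            if not is_policy:
                agent.update(choice, reward)
            if better is not None:
                consec_incorrect = (consec_incorrect + 1
                                    if choice != better else 0)
        else:
            reward, volume = 0, 0.0

        rows.append((rat_id, session_id, trial_index, block_ordinal,
                     block_trial, contrast, ACTIONS[choice], reward,
                     volume, valid,
                     "none" if better is None else ACTIONS[better]))

        if block_trial >= length:
            deferred = (config.defer_on_incorrect_streak
                        and contrast != "NC"
                        and consec_incorrect >= DEFER_STREAK)
            if not deferred:
                contrast, better, length = _draw_block(rng, contrast,
                                                       last_better)
                if better is not None:
                    last_better = better
                block_ordinal += 1
                block_trial = 0
                consec_incorrect = 0

    # better_side is task-internal ground truth (used by the behavioral
    # analyses); it is not part of the canonical on-disk schema and is
    # dropped by write_trials.
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS + ("better_side",))
    trace = None
    if not is_policy:
        valid_trials = trials[trials["valid"]]
        if len(valid_trials):
            _, trace = session_negloglik(model, params, valid_trials)
            trace.index = valid_trials.index
    return trials, trace


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortConfig:
    """Specification of a simulated multi-rat cohort.

    ``group_param_distributions`` maps group label -> parameter name ->
    ``(loc, scale)`` of a normal distribution truncated to the parameter's
    bounds, on the parameter's native scale.  ``scale = 0`` pins the
    parameter at ``loc``.
    """

    group_labels: tuple
    n_rats_per_group: int
    sessions_per_rat: int
    trials_per_session: int
    generating_model: str
    group_param_distributions: Mapping[str, Mapping[str, tuple]]
    seed: int = 0
    invalid_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.group_labels:
            raise ValueError("at least one group required")
        if min(self.n_rats_per_group, self.sessions_per_rat,
               self.trials_per_session) < 1:
            raise ValueError("cohort dimensions must be >= 1")
        get_model(self.generating_model)
        for g in self.group_labels:
            if g not in self.group_param_distributions:
                raise ValueError(f"no parameter distribution for group {g!r}")


def _draw_param(rng: np.random.Generator, loc: float, scale: float,
                lo: float, hi: float) -> float:
    hi_eff = min(hi, 20.0) if np.isinf(hi) else hi
    if scale == 0.0:
        if not lo <= loc <= hi_eff:
            raise ValueError(
                f"degenerate distribution at {loc} outside bounds [{lo}, {hi_eff}]")
        return float(loc)
    a, b = (lo - loc) / scale, (hi_eff - loc) / scale
    if a >= b:
        raise ValueError("truncation interval is empty")
    return float(stats.truncnorm.rvs(a, b, loc=loc, scale=scale,
                                     random_state=rng))


def generate_cohort(cohort: CohortConfig,
                    task_config: TaskConfig | None = None):
    """Simulate a cohort of rats with group-specific generating parameters.

    Each rat's parameters are drawn once from its group's truncated-normal
    distributions and held fixed across that rat's sessions.  Returns
    ``(trials, true_params)``: the concatenated trial table and one row of
    generating parameters per rat (for recovery analyses).
    """
    spec = get_model(cohort.generating_model)
    rng = np.random.default_rng(cohort.seed)
    task_config = task_config or TaskConfig(
        n_trials=cohort.trials_per_session, invalid_rate=cohort.invalid_rate)

    frames, param_rows = [], []
    for group in cohort.group_labels:
        dists = cohort.group_param_distributions[group]
        for i in range(cohort.n_rats_per_group):
            rat_id = f"{group}_r{i:02d}"
            values = {}
            for name, (lo, hi) in zip(spec.param_names, spec.bounds):
                if name not in dists:
                    raise ValueError(
                        f"group {group!r} missing distribution for {name!r}")
                loc, scale = dists[name]
                values[name] = _draw_param(rng, loc, scale, lo, hi)
            params = make_params(cohort.generating_model, values)
            param_rows.append({"rat_id": rat_id, "group": group, **values})
            for s in range(cohort.sessions_per_rat):
                sess_seed = int(rng.integers(2 ** 31))
                trials, _ = simulate_session(
                    cohort.generating_model, params, task_config,
                    seed=sess_seed, rat_id=rat_id,
                    session_id=f"{rat_id}_s{s:02d}")
                frames.append(trials)
    trials = pd.concat(frames, ignore_index=True)
    return trials, pd.DataFrame(param_rows)


# ---------------------------------------------------------------------------
# trial-table I/O


def validate_trials(df: pd.DataFrame) -> None:
    """Schema-check a trial table; raises ValueError naming offending rows."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    errors = []
    for col, domain in (("contrast_label", set(CONTRAST_LABELS)),
                        ("choice", set(ACTIONS)),
                        ("reward", {0, 1})):
        bad = ~df[col].isin(domain)
        if bad.any():
            rows = df.index[bad][:5].tolist()
            errors.append(f"{col} outside {sorted(map(str, domain))} "
                          f"at rows {rows}")
    rewarded = df["reward"] == 1
    if ((df.loc[rewarded, "reward_volume"] <= 0).any()
            or (df.loc[~rewarded, "reward_volume"] != 0).any()):
        errors.append("reward_volume must be > 0 iff reward = 1")
    for (_, _), grp in df.groupby(["rat_id", "session_id"], sort=False):
        ti = grp["trial_index"].to_numpy()
        if (np.diff(ti) <= 0).any():
            errors.append(
                f"non-monotone trial_index in session {grp['session_id'].iat[0]!r}")
            break
    if errors:
        raise ValueError("trial table validation failed: " + "; ".join(errors))


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table as UTF-8 CSV with the canonical column order."""
    if len(df):
        validate_trials(df)
    df = df.reindex(columns=list(TRIAL_COLUMNS))
    df.to_csv(path, index=False, encoding="utf-8")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV."""
    df = pd.read_csv(
        path,
        dtype={"rat_id": str, "session_id": str},
        encoding="utf-8",
    )
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if len(df) == 0:
        return df.reindex(columns=list(TRIAL_COLUMNS))
    df["valid"] = df["valid"].astype(bool)
    for col in ("trial_index", "block_ordinal", "block_trial", "reward"):
        df[col] = df[col].astype(int)
    df["reward_volume"] = df["reward_volume"].astype(float)
    validate_trials(df)
    return df


def drop_invalid(df: pd.DataFrame) -> pd.DataFrame:
    """Remove invalid trials (the convention for every analysis)."""
    return df[df["valid"].astype(bool)].reset_index(drop=True)


def session_iter(df: pd.DataFrame):
    """Yield ``((rat_id, session_id), session_frame)`` in stable order,
    trials sorted by trial_index within each session."""
    srt = df.sort_values(["rat_id", "session_id", "trial_index"],
                         kind="stable")
    for key, grp in srt.groupby(["rat_id", "session_id"], sort=True):
        yield key, grp
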