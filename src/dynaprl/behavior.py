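"""Model-independent behavioral battery.

Win-stay (WS): a rewarded choice is repeated on the next trial.
Lose-shift (LS): an unrewarded choice is followed by the other lever.
Probabilities are computed from *pooled counts*: per rat, numerators and
denominators are summed across all sessions before dividing (equivalently, a
trial-weighted mean of per-session probabilities).

Strata:

* phase — ``early`` (block trials 1-6 after a transition) vs ``late``
  (trial 7 to block end);
* contrast — block type HC / LC / NC;
* action_type — whether the outcome trial's choice was the block's higher-
  (``better``) or lower- (``worse``) probability lever; undefined in
  no-contrast blocks, which are therefore excluded from action-type strata.

A stay/shift transition is attributed to the context (block, phase, action
type) of its *outcome* trial, i.e. the first trial of the consecutive pair;
pairs spanning session boundaries are excluded, and invalid trials are
dropped before pairing.

The perseveration curve tracks, for 5 trials before and 12 trials after each
block transition, the probability of choosing the lever that was "correct"
(higher probability) before the reversal.  In no-contrast blocks one lever
is designated correct uniformly at random (seeded).
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .task import drop_invalid

__all__ = ["transition_pairs", "ws_ls_probabilities",
           "action_difference_score", "perseveration_curve"]

EARLY_MAX_TRIAL = 6
METRICS = ("WS", "LS", "lose-stay", "win-shift")
PRE_REVERSAL_TRIALS = 5
POST_REVERSAL_TRIALS = 12


def attach_phase(trials: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``phase`` column (early/late by block trial)."""
    out = trials.copy()
    out["phase"] = np.where(out["block_trial"] <= EARLY_MAX_TRIAL,
                            "early", "late")
    return out


def transition_pairs(trials: pd.DataFrame) -> pd.DataFrame:
    """One row per consecutive valid-trial pair within a session.

    Columns describe the outcome trial (the first of the pair) plus
    ``next_choice`` and ``stay``.  ``action_type`` is better/worse/undef.
    """
    df = drop_invalid(trials).sort_values(
        ["rat_id", "session_id", "trial_index"], kind="stable")
    df = attach_phase(df)
    same_sess = ((df["rat_id"] == df["rat_id"].shift(-1))
                 & (df["session_id"] == df["session_id"].shift(-1)))
    df["next_choice"] = df["choice"].shift(-1)
    pairs = df[same_sess].copy()
    pairs["stay"] = pairs["choice"] == pairs["next_choice"]
    if "better_side" in pairs.columns:
        bs = pairs["better_side"]
        pairs["action_type"] = np.select(
            [bs == "none", pairs["choice"] == bs],
            ["undef", "better"], default="worse")
    else:
        pairs["action_type"] = "undef"
    return pairs.reset_index(drop=True)


def _metric_masks(pairs: pd.DataFrame, metric: str):
    """(numerator mask, denominator mask) for one WS/LS-family metric."""
    win = pairs["reward"] == 1
    stay = pairs["stay"]
    if metric == "WS":
        return win & stay, win
    if metric == "win-shift":
        return win & ~stay, win
    if metric == "LS":
        return ~win & ~stay, ~win
    if metric == "lose-stay":
        return ~win & stay, ~win
    raise ValueError(f"unknown metric {metric!r}")


def ws_ls_probabilities(trials: pd.DataFrame,
                        stratify_by: Iterable[str] = ("phase", "contrast",
                                                      "action_type"),
                        metrics: Iterable[str] = ("WS", "LS", "lose-stay"),
                        ) -> pd.DataFrame:
    """Pooled-count WS/LS-family probabilities per rat and stratum.

    Returns a tidy table with one row per (rat, metric, phase, contrast,
    action_type) cell, including the ``all`` marginal of each stratification
    dimension, with ``numerator``, ``denominator``, ``probability`` and a
    ``defined`` flag (False where the denominator is zero; the probability
    is then NaN, never silently dropped).
    """
    stratify_by = set(stratify_by)
    unknown = stratify_by - {"phase", "contrast", "action_type"}
    if unknown:
        raise ValueError(f"unknown strata {sorted(unknown)}")
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}")
    if "action_type" in stratify_by and "better_side" not in trials.columns:
        raise ValueError(
            "action_type stratification needs a better_side column")

    pairs = transition_pairs(trials)
    rats = sorted(trials["rat_id"].unique())
    phases = ["early", "late", "all"] if "phase" in stratify_by else ["all"]
    contrasts = (["HC", "LC", "NC", "all"] if "contrast" in stratify_by
                 else ["all"])
    atypes = (["better", "worse", "all"] if "action_type" in stratify_by
              else ["all"])

    rows = []
    for metric, phase, contrast, atype in itertools.product(
            metrics, phases, contrasts, atypes):
        num_mask, den_mask = _metric_masks(pairs, metric)
        sel = pd.Series(True, index=pairs.index)
        if phase != "all":
            sel &= pairs["phase"] == phase
        if contrast != "all":
            sel &= pairs["contrast_label"] == contrast
        if atype != "all":
            sel &= pairs["action_type"] == atype
        num = pairs.loc[sel & num_mask].groupby("rat_id").size()
        den = pairs.loc[sel & den_mask].groupby("rat_id").size()
        for rat in rats:
            n = int(num.get(rat, 0))
            d = int(den.get(rat, 0))
            rows.append({"rat_id": rat, "metric": metric, "phase": phase,
                         "contrast": contrast, "action_type": atype,
                         "numerator": n, "denominator": d,
                         "probability": n / d if d else np.nan,
                         "defined": d > 0})
    return pd.DataFrame(rows)


def action_difference_score(table: pd.DataFrame) -> pd.DataFrame:
    """Better-minus-worse probability difference per (rat, metric, phase,
    contrast); missing or undefined cells yield a flagged NaN score."""
    keys = ["rat_id", "metric", "phase", "contrast"]
    sub = table[table["action_type"].isin(["better", "worse"])]
    wide = sub.pivot_table(index=keys, columns="action_type",
                           values="probability", aggfunc="first",
                           dropna=False)
    wide = wide.reindex(columns=["better", "worse"])
    out = wide.reset_index()
    out["score"] = out["better"] - out["worse"]
    out["defined"] = out["score"].notna()
    return out


def perseveration_curve(trials: pd.DataFrame, seed: int | None = None,
                        rat_groups: Mapping[str, str] | None = None,
                        convention: str = "perseveration") -> pd.DataFrame:
    """Choice probability around block transitions.

    For every pair of consecutive blocks within a session, relative trials
    -5..-1 index the last five valid trials of the pre-reversal block and
    +1..+12 the first twelve of the post-reversal block.  Under the default
    ``"perseveration"`` convention the score at every relative trial is the
    fraction of transitions on which the choice matched the lever that was
    correct *before* the reversal.  ``convention="correct"`` instead scores
    choice of the current block's correct lever throughout.  NC blocks get a
    seeded random correct lever.

    Returns a tidy frame (group, rel_trial, p, n); group is ``all`` when no
    ``rat_groups`` mapping is supplied.  Sessions with no block transition
    contribute nothing.
    """
    if convention not in ("perseveration", "correct"):
        raise ValueError("convention must be 'perseveration' or 'correct'")
    if "better_side" not in trials.columns:
        raise ValueError("perseveration needs a better_side column")
    rng = np.random.default_rng(seed)
    df = drop_invalid(trials)

    counts: dict[tuple, np.ndarray] = {}
    rel_range = list(range(-PRE_REVERSAL_TRIALS, 0)) + \
        list(range(1, POST_REVERSAL_TRIALS + 1))

    def _acc(group):
        if group not in counts:
            counts[group] = np.zeros((2, len(rel_range)))
        return counts[group]

    for (rat, _sess), sess in df.groupby(["rat_id", "session_id"],
                                         sort=True):
        group = rat_groups.get(rat, "all") if rat_groups else "all"
        blocks = [b for _, b in sess.groupby("block_ordinal", sort=True)]
        if len(blocks) < 2:
            continue
        correct = []
        for b in blocks:
            side = b["better_side"].iat[0]
            if side == "none":
                side = ("left", "right")[rng.integers(2)]
            correct.append(side)
        arr = _acc(group)
        for bi in range(len(blocks) - 1):
            pre, post = blocks[bi], blocks[bi + 1]
            ref_pre = correct[bi]
            ref_post = ref_pre if convention == "perseveration" \
                else correct[bi + 1]
            pre_choices = pre["choice"].to_numpy()[-PRE_REVERSAL_TRIALS:]
            for j, ch in enumerate(pre_choices[::-1]):
                col = PRE_REVERSAL_TRIALS - 1 - j  # rel trial -(j+1)
                arr[0, col] += ch == ref_pre
                arr[1, col] += 1
            post_choices = post["choice"].to_numpy()[:POST_REVERSAL_TRIALS]
            for j, ch in enumerate(post_choices):
                col = PRE_REVERSAL_TRIALS + j
                arr[0, col] += ch == ref_post
                arr[1, col] += 1

    rows = []
    for group in sorted(counts):
        arr = counts[group]
        for j, rel in enumerate(rel_range):
            n = int(arr[1, j])
            rows.append({"group": group, "rel_trial": rel,
                         "p": arr[0, j] / n if n else np.nan, "n": n})
    return pd.DataFrame(rows)
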