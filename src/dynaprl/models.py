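"""Trial-by-trial reinforcement-learning models for two-lever choice data.

Four model kernels are implemented, all sharing a softmax choice rule over
two action values:

* ``standard`` — Rescorla-Wagner delta rule: ``RPE_t = R_t - V(c_t)``,
  ``V(c_t) += alpha * RPE_t``.  Free parameters: learning rate ``alpha``
  and inverse temperature ``beta``.
* ``avg_rpe`` — the chosen value is updated by an exponentially averaged
  prediction error, ``avgRPE_t = alpha * RPE_t + hW * avgRPE_{t-1}``, with
  history weight ``hW`` bounded in [0, 0.75].  With ``hW = 0`` this reduces
  exactly to the standard model.
* ``grs`` — a global-reward-state model: a reward trace
  ``Rtrace_t = Rtrace_{t-1} + (R_{t-1} - Rtrace_{t-1}) * alpha_R`` enters the
  prediction error as ``RPE_t = R_t + w_R * Rtrace_t - V(c_t)`` with
  ``w_R`` in [-1, 1].
* ``asym`` — a five-parameter asymmetric model with separate learning rates
  for rewarded (``alpha_pos``) and unrewarded (``alpha_neg``) choices, and
  multiplicative decay of the *unchosen* value by ``gamma_pos`` after a win
  or ``gamma_neg`` after a loss.  ``asym_ch`` adds a choice-history
  (stickiness) term ``phi`` to the softmax argument.

Values are initialised to zero for both actions at the start of each session
and carry over block transitions within a session; sessions are independent.
Reward enters the updates as binary 0/1 regardless of delivered volume.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels

ACTIONS = ("left", "right")

__all__ = [
    "MODELS",
    "ModelSpec",
    "StandardParams",
    "AvgRpeParams",
    "GrsParams",
    "AsymParams",
    "softmax_prob",
    "step_standard",
    "step_avg_rpe",
    "step_grs",
    "step_asymmetric",
    "session_negloglik",
    "make_params",
]


def _check_bounds(name: str, value: float, lo: float, hi: float) -> None:
    if not np.isfinite(value) or not (lo <= value <= hi):
        raise ValueError(f"{name}={value!r} outside bounds [{lo}, {hi}]")


@dataclass(frozen=True)
class StandardParams:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        _check_bounds("alpha", self.alpha, 0.0, 1.0)
        _check_bounds("beta", self.beta, 0.0, np.inf)


@dataclass(frozen=True)
class AvgRpeParams:
    alpha: float
    beta: float
    hw: float

    def __post_init__(self) -> None:
        _check_bounds("alpha", self.alpha, 0.0, 1.0)
        _check_bounds("beta", self.beta, 0.0, np.inf)
        _check_bounds("hw", self.hw, 0.0, 0.75)


@dataclass(frozen=True)
class GrsParams:
    alpha: float
    beta: float
    alpha_r: float
    w_r: float

    def __post_init__(self) -> None:
        _check_bounds("alpha", self.alpha, 0.0, 1.0)
        _check_bounds("beta", self.beta, 0.0, np.inf)
        _check_bounds("alpha_r", self.alpha_r, 0.0, 1.0)
        _check_bounds("w_r", self.w_r, -1.0, 1.0)


@dataclass(frozen=True)
class AsymParams:
    alpha_pos: float
    alpha_neg: float
    gamma_pos: float
    gamma_neg: float
    beta: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        for nm in ("alpha_pos", "alpha_neg", "gamma_pos", "gamma_neg"):
            _check_bounds(nm, getattr(self, nm), 0.0, 1.0)
        _check_bounds("beta", self.beta, 0.0, np.inf)
        if not np.isfinite(self.phi):
            raise ValueError("phi must be finite")


@dataclass(frozen=True)
class ModelSpec:
    """Registry entry: parameter names and fitting bounds for one model."""

    name: str
    param_cls: type
    param_names: tuple
    bounds: tuple  # (lo, hi) per parameter, in param_names order

    @property
    def n_params(self) -> int:
        return len(self.param_names)


# beta is bounded at 20 for fitting: with values in [0, 1] the softmax is
# effectively saturated well below that.
_BETA_FIT = (0.0, 20.0)

MODELS: dict[str, ModelSpec] = {
    "standard": ModelSpec("standard", StandardParams, ("alpha", "beta"),
                          ((0.0, 1.0), _BETA_FIT)),
    "avg_rpe": ModelSpec("avg_rpe", AvgRpeParams, ("alpha", "beta", "hw"),
                         ((0.0, 1.0), _BETA_FIT, (0.0, 0.75))),
    "grs": ModelSpec("grs", GrsParams, ("alpha", "beta", "alpha_r", "w_r"),
                     ((0.0, 1.0), _BETA_FIT, (0.0, 1.0), (-1.0, 1.0))),
    "asym": ModelSpec("asym", AsymParams,
                      ("alpha_pos", "alpha_neg", "gamma_pos", "gamma_neg", "beta"),
                      ((0.0, 1.0),) * 4 + (_BETA_FIT,)),
    "asym_ch": ModelSpec("asym_ch", AsymParams,
                         ("alpha_pos", "alpha_neg", "gamma_pos", "gamma_neg",
                          "beta", "phi"),
                         ((0.0, 1.0),) * 4 + (_BETA_FIT, (-5.0, 5.0))),
}


def get_model(model: str) -> ModelSpec:
    try:
        return MODELS[model]
    except KeyError:
        raise ValueError(
            f"unknown model {model!r}; available: {sorted(MODELS)}") from None


def make_params(model: str, values: Mapping[str, float] | Sequence[float]):
    """Build a validated parameter object for ``model``.

    ``values`` may be a name->value mapping or a sequence in the model's
    canonical parameter order.
    """
    spec = get_model(model)
    if isinstance(values, Mapping):
        kwargs = {k: float(values[k]) for k in spec.param_names}
    else:
        if len(values) != spec.n_params:
            raise ValueError(
                f"{model} expects {spec.n_params} parameters, got {len(values)}")
        kwargs = dict(zip(spec.param_names, map(float, values)))
    return spec.param_cls(**kwargs)


def params_to_dict(params) -> dict[str, float]:
    return {f.name: getattr(params, f.name) for f in fields(params)}


# ---------------------------------------------------------------------------
# single-step operations


def softmax_prob(values: Sequence[float], beta: float) -> np.ndarray:
    """Softmax choice probabilities over a pair of action values.

    Computed by shifting by the maximum value, so large ``beta * value``
    products cannot overflow.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite action values")
    if beta < 0 or not np.isfinite(beta):
        raise ValueError("beta must be finite and >= 0")
    z = beta * v
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def step_standard(values, choice: int, reward: int, params: StandardParams):
    """One delta-rule update; returns (new values, RPE)."""
    v = np.array(values, dtype=float)
    rpe = reward - v[choice]
    v[choice] += params.alpha * rpe
    return v, rpe


def step_avg_rpe(values, prev_avg_rpe: float, choice: int, reward: int,
                 params: AvgRpeParams):
    """One averaged-RPE update; returns (new values, RPE, new avgRPE)."""
    v = np.array(values, dtype=float)
    rpe = reward - v[choice]
    avg = params.alpha * rpe + params.hw * prev_avg_rpe
    v[choice] += avg
    return v, rpe, avg


def step_grs(values, rtrace: float, choice: int, reward: int,
             previous_reward: int, params: GrsParams):
    """One reward-trace update; returns (new values, RPE, new Rtrace).

    The reward trace is advanced from the *previous* trial's reward before
    the current prediction error is formed.
    """
    v = np.array(values, dtype=float)
    rt = rtrace + (previous_reward - rtrace) * params.alpha_r
    rpe = reward + params.w_r * rt - v[choice]
    v[choice] += params.alpha * rpe
    return v, rpe, rt


def step_asymmetric(values, choice: int, reward: int, params: AsymParams):
    """One asymmetric update (chosen learning + unchosen decay); returns
    (new values, RPE)."""
    v = np.array(values, dtype=float)
    rpe = reward - v[choice]
    if reward == 1:
        v[choice] += params.alpha_pos * rpe
        v[1 - choice] *= params.gamma_pos
    else:
        v[choice] += params.alpha_neg * rpe
        v[1 - choice] *= params.gamma_neg
    return v, rpe


# ---------------------------------------------------------------------------
# session likelihood


def _session_arrays(session) -> tuple[np.ndarray, np.ndarray]:
    """Extract int8 choice/reward arrays from a trial table, dropping invalid
    trials.  Accepts a DataFrame with (choice, reward[, valid]) columns or a
    (choices, rewards) array pair with choices already coded 0/1."""
    if isinstance(session, pd.DataFrame):
        df = session
        if "valid" in df.columns:
            df = df[df["valid"].astype(bool)]
        ch = df["choice"]
        if ch.dtype == object:
            bad = ~ch.isin(ACTIONS)
            if bad.any():
                raise ValueError(f"invalid choice labels: {ch[bad].unique()!r}")
            choices = (ch == "right").to_numpy(dtype=np.int8)
        else:
            choices = ch.to_numpy(dtype=np.int8)
        rewards = df["reward"].to_numpy(dtype=np.int8)
    else:
        choices = np.asarray(session[0], dtype=np.int8)
        rewards = np.asarray(session[1], dtype=np.int8)
    if choices.size == 0:
        raise ValueError("session has no valid trials")
    if not np.isin(choices, (0, 1)).all() or not np.isin(rewards, (0, 1)).all():
        raise ValueError("choices and rewards must be binary")
    return choices, rewards


def session_negloglik(model: str, params, session, return_trace: bool = True):
    """Negative log-likelihood of one session's choices under ``model``.

    Values start at zero for both actions; trials are processed in order and
    invalid trials are dropped first.  Returns ``(nll, trace)`` where
    ``trace`` is a per-trial DataFrame with the pre-choice values ``v_left``
    and ``v_right``, the signed prediction error ``rpe``, the probability
    assigned to the taken action ``p_choice``, and the model's auxiliary
    trace (``avg_rpe`` or ``rtrace``) where one exists.  With
    ``return_trace=False`` only the scalar nLL is returned.
    """
    spec = get_model(model)
    if not isinstance(params, spec.param_cls):
        params = make_params(model, params)
    choices, rewards = _session_arrays(session)

    aux_name = None
    if model == "standard":
        if return_trace:
            out = _kernels.nll_standard_trace(choices, rewards,
                                              params.alpha, params.beta)
        else:
            return float(_kernels.nll_standard(choices, rewards,
                                               params.alpha, params.beta))
    elif model == "avg_rpe":
        aux_name = "avg_rpe"
        if return_trace:
            out = _kernels.nll_avg_rpe_trace(choices, rewards, params.alpha,
                                             params.beta, params.hw)
        else:
            return float(_kernels.nll_avg_rpe(choices, rewards, params.alpha,
                                              params.beta, params.hw))
    elif model == "grs":
        aux_name = "rtrace"
        if return_trace:
            out = _kernels.nll_grs_trace(choices, rewards, params.alpha,
                                         params.beta, params.alpha_r, params.w_r)
        else:
            return float(_kernels.nll_grs(choices, rewards, params.alpha,
                                          params.beta, params.alpha_r,
                                          params.w_r))
    elif model in ("asym", "asym_ch"):
        use_hist = model == "asym_ch"
        args = (choices, rewards, params.alpha_pos, params.alpha_neg,
                params.gamma_pos, params.gamma_neg, params.beta,
                params.phi, use_hist)
        if return_trace:
            out = _kernels.nll_asym_trace(*args)
        else:
            return float(_kernels.nll_asym(*args))
    else:  # pragma: no cover - registry and dispatch kept in sync
        raise ValueError(f"unknown model {model!r}")

    nll = float(out[0])
    if not np.isfinite(nll):
        raise FloatingPointError(f"non-finite nLL for model {model!r}")
    cols = {"v_left": out[1], "v_right": out[2], "rpe": out[3]}
    if aux_name is not None:
        cols[aux_name] = out[4]
        cols["p_choice"] = out[5]
    else:
        cols["p_choice"] = out[4]
    trace = pd.DataFrame(cols)
    trace.insert(0, "choice", choices)
    trace.insert(1, "reward", rewards)
    if not np.isfinite(trace["rpe"].to_numpy()).all():
        raise FloatingPointError("non-finite values in latent trace")
    return nll, trace
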