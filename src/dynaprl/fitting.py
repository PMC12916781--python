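"""Per-session maximum-likelihood fitting, BIC model comparison, and
parameter / model recovery harnesses.

Each session is fit independently by bounded local optimisation (L-BFGS-B)
restarted from ``n_restarts`` uniform-random points inside the parameter
bounds; the restart with the lowest negative log-likelihood is kept.  Models
are compared by the Bayesian information criterion

    BIC = 2 * nLL + nParams * log(nObs)

computed per session with nObs the number of valid trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _kernels
from .models import MODELS, get_model, _session_arrays
from .task import TaskConfig, session_iter, simulate_session

__all__ = ["FitResult", "RecoveryReport", "bic", "fit_session_mle",
           "fit_sessions", "compare_models", "compare_from_fits",
           "parameter_recovery", "model_recovery"]


def bic(nll: float, n_params: int, n_obs: int) -> float:
    """Bayesian information criterion, ``2*nLL + nParams*ln(nObs)``."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return 2.0 * nll + n_params * np.log(n_obs)


@dataclass(frozen=True)
class FitResult:
    model: str
    session_id: str
    params: dict
    nll: float
    n_obs: int
    n_params: int
    bic: float
    n_restarts: int
    converged: bool
    rat_id: str = ""

    def to_row(self) -> dict:
        row = {"model": self.model, "rat_id": self.rat_id,
               "session_id": self.session_id, "nll": self.nll,
               "n_obs": self.n_obs, "n_params": self.n_params,
               "bic": self.bic, "n_restarts": self.n_restarts,
               "converged": self.converged}
        row.update(self.params)
        return row


def _nll_fn(model: str, choices: np.ndarray, rewards: np.ndarray):
    """Closure computing the session nLL from a raw parameter vector."""
    if model == "standard":
        return lambda x: _kernels.nll_standard(choices, rewards, x[0], x[1])
    if model == "avg_rpe":
        return lambda x: _kernels.nll_avg_rpe(choices, rewards, x[0], x[1], x[2])
    if model == "grs":
        return lambda x: _kernels.nll_grs(choices, rewards, x[0], x[1], x[2], x[3])
    if model == "asym":
        return lambda x: _kernels.nll_asym(choices, rewards, x[0], x[1], x[2],
                                           x[3], x[4], 0.0, False)
    if model == "asym_ch":
        return lambda x: _kernels.nll_asym(choices, rewards, x[0], x[1], x[2],
                                           x[3], x[4], x[5], True)
    raise ValueError(f"unknown model {model!r}")


def draw_uniform_params(model: str, rng: np.random.Generator,
                        overrides: Mapping[str, tuple] | None = None) -> dict:
    """Draw one parameter set uniformly inside the model's fitting bounds,
    with optional per-parameter ``(lo, hi)`` range overrides."""
    spec = get_model(model)
    overrides = overrides or {}
    out = {}
    for name, (lo, hi) in zip(spec.param_names, spec.bounds):
        lo, hi = overrides.get(name, (lo, hi))
        out[name] = float(rng.uniform(lo, hi))
    return out


def fit_session_mle(model: str, session, n_restarts: int = 10,
                    seed: int | None = None, session_id: str = "",
                    rat_id: str = "") -> FitResult:
    """Maximum-likelihood fit of one session by multi-restart L-BFGS-B.

    Starts are uniform inside the bounds, drawn from ``seed``; the result is
    deterministic given (data, seed).  A fit is marked unconverged only if
    every restart's optimiser failed.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    spec = get_model(model)
    choices, rewards = _session_arrays(session)
    fn = _nll_fn(model, choices, rewards)
    rng = np.random.default_rng(seed)
    bounds = list(spec.bounds)

    best_x, best_nll, any_success = None, np.inf, False
    for _ in range(n_restarts):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = minimize(fn, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500})
        any_success = any_success or bool(res.success)
        if res.fun < best_nll:
            best_nll, best_x = float(res.fun), res.x
    if best_x is None or not np.isfinite(best_nll):
        raise RuntimeError(f"all restarts failed for model {model!r}")

    params = dict(zip(spec.param_names, map(float, best_x)))
    n_obs = int(choices.size)
    return FitResult(model=model, session_id=session_id, params=params,
                     nll=best_nll, n_obs=n_obs, n_params=spec.n_params,
                     bic=bic(best_nll, spec.n_params, n_obs),
                     n_restarts=n_restarts, converged=any_success,
                     rat_id=rat_id)


def fit_sessions(trials: pd.DataFrame, model: str, n_restarts: int = 10,
                 seed: int | None = None) -> pd.DataFrame:
    """Fit every (rat, session) in a trial table; one result row each."""
    rng = np.random.default_rng(seed)
    rows = []
    for (rat, sess), grp in session_iter(trials):
        fr = fit_session_mle(model, grp, n_restarts=n_restarts,
                             seed=int(rng.integers(2 ** 31)),
                             session_id=sess, rat_id=rat)
        rows.append(fr.to_row())
    return pd.DataFrame(rows)


def compare_models(trials: pd.DataFrame, models: Sequence[str],
                   n_restarts: int = 10, seed: int | None = None,
                   include_nonconverged: bool = True) -> dict:
    """Fit several models to every session and compare them by BIC.

    Returns a dict with ``fits`` (one row per session per model),
    ``per_session`` (wide BIC table plus the per-session winner; ties go to
    the model with fewer parameters) and ``summed`` (total BIC per model,
    over sessions where every model converged unless
    ``include_nonconverged``).
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    if len(trials) == 0:
        raise ValueError("no sessions to fit")
    fits = pd.concat(
        [fit_sessions(trials, m, n_restarts=n_restarts, seed=seed)
         for m in models], ignore_index=True)
    return compare_from_fits(fits, models,
                             include_nonconverged=include_nonconverged)


def compare_from_fits(fits: pd.DataFrame, models: Sequence[str],
                      include_nonconverged: bool = True) -> dict:
    """BIC comparison from an existing per-session fit table (see
    :func:`compare_models` for the output contract)."""
    models = list(models)
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    wide = fits.pivot_table(index=["rat_id", "session_id"], columns="model",
                            values="bic")[models]
    conv = fits.pivot_table(index=["rat_id", "session_id"], columns="model",
                            values="converged", aggfunc="all")[models]
    n_par = {m: MODELS[m].n_params for m in models}

    def _winner(row):
        best = row.min()
        tied = [m for m in models if np.isclose(row[m], best)]
        return min(tied, key=lambda m: (n_par[m], m))

    per_session = wide.copy()
    per_session["winner"] = wide.apply(_winner, axis=1)
    per_session["all_converged"] = conv.all(axis=1)

    usable = per_session if include_nonconverged else \
        per_session[per_session["all_converged"]]
    summed = usable[models].sum(axis=0).rename("summed_bic")
    return {"fits": fits, "per_session": per_session.reset_index(),
            "summed": summed}


@dataclass
class RecoveryReport:
    """Simulate-fit-recover diagnostics.

    ``params`` holds one row per simulated session with true and recovered
    values; ``summary`` one row per parameter (Pearson r, bias, RMSE);
    ``confusion`` the generating-model x best-fitting-model BIC count matrix
    (model recovery only).
    """

    params: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None
    confusion: pd.DataFrame | None = None
    summed_bic: pd.DataFrame | None = None


def parameter_recovery(model: str, n_draws: int, trials_per_session: int = 500,
                       seed: int | None = None, n_restarts: int = 10,
                       draw_overrides: Mapping[str, tuple] | None = None,
                       task_config: TaskConfig | None = None) -> RecoveryReport:
    """Parameter recovery: simulate sessions at known parameters, refit, and
    correlate true with recovered values.

    By default the inverse temperature is drawn in [1, 8] (very low beta
    makes every other parameter unidentifiable); other parameters are drawn
    uniformly over their full bounds.
    """
    if trials_per_session < 100:
        raise ValueError("recovery needs >= 100 trials per session")
    overrides = {"beta": (1.0, 8.0)}
    overrides.update(draw_overrides or {})
    rng = np.random.default_rng(seed)
    cfg = task_config or TaskConfig(n_trials=trials_per_session)
    spec = get_model(model)

    rows = []
    for i in range(n_draws):
        true = draw_uniform_params(model, rng, overrides)
        trials, _ = simulate_session(model, true, cfg,
                                     seed=int(rng.integers(2 ** 31)),
                                     session_id=f"draw{i:03d}")
        fr = fit_session_mle(model, trials, n_restarts=n_restarts,
                             seed=int(rng.integers(2 ** 31)),
                             session_id=f"draw{i:03d}")
        row = {"draw": i, "converged": fr.converged}
        for p in spec.param_names:
            row[f"{p}_true"] = true[p]
            row[f"{p}_fit"] = fr.params[p]
        rows.append(row)
    params = pd.DataFrame(rows)

    summary = []
    for p in spec.param_names:
        t = params[f"{p}_true"].to_numpy()
        f = params[f"{p}_fit"].to_numpy()
        r = float(np.corrcoef(t, f)[0, 1]) if np.std(t) > 0 and np.std(f) > 0 \
            else np.nan
        summary.append({"param": p, "pearson_r": r,
                        "bias": float(np.mean(f - t)),
                        "rmse": float(np.sqrt(np.mean((f - t) ** 2)))})
    return RecoveryReport(params=params, summary=pd.DataFrame(summary))


def model_recovery(models: Sequence[str], n_sessions: int,
                   trials_per_session: int = 500, seed: int | None = None,
                   n_restarts: int = 10,
                   draw_overrides: Mapping[str, Mapping[str, tuple]] | None = None,
                   task_config: TaskConfig | None = None) -> RecoveryReport:
    """Model recovery: simulate ``n_sessions`` per generating model, fit all
    candidate models to each, and tabulate the per-session BIC winner into a
    confusion matrix (rows = generating model, columns = best-fitting model).

    ``draw_overrides`` optionally restricts the generating-parameter ranges
    per model (e.g. ``{"avg_rpe": {"hw": (0.3, 0.75)}}`` to keep the history
    weight away from the nested standard model).
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("need at least two models")
    rng = np.random.default_rng(seed)
    cfg = task_config or TaskConfig(n_trials=trials_per_session)
    overrides = draw_overrides or {}

    confusion = pd.DataFrame(0, index=models, columns=models)
    summed = pd.DataFrame(0.0, index=models, columns=models)
    n_par = {m: MODELS[m].n_params for m in models}
    for gen in models:
        ov = {"beta": (1.0, 8.0)}
        ov.update(overrides.get(gen, {}))
        for i in range(n_sessions):
            true = draw_uniform_params(gen, rng, ov)
            trials, _ = simulate_session(gen, true, cfg,
                                         seed=int(rng.integers(2 ** 31)))
            bics = {}
            for m in models:
                fr = fit_session_mle(m, trials, n_restarts=n_restarts,
                                     seed=int(rng.integers(2 ** 31)))
                bics[m] = fr.bic
                summed.loc[gen, m] += fr.bic
            best = min(bics, key=lambda m: (bics[m], n_par[m], m))
            confusion.loc[gen, best] += 1
    confusion.index.name = "generating"
    confusion.columns.name = "best_fit"
    return RecoveryReport(confusion=confusion, summed_bic=summed)
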