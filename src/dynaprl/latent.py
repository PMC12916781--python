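"""Model-dependent analyses of latent task variables.

Three latent series drive these analyses:

* the signed RPE from the fitted standard model, combined across the
  current and previous trial as ``wRPE_t = k*RPE_t + (1-k)*RPE_{t-1}`` and
  scanned over ``k`` in {0.500, 0.525, ..., 1.000} to ask how much weight
  the previous trial's surprise carries in stay/shift decisions;
* ``|avgRPE|`` — the absolute exponentially averaged RPE from the fitted
  avgRPE model, a proxy for the animal's uncertainty state;
* ``GRS`` — the reward trace of the fitted global-reward-state model, a
  proxy for perceived environmental richness.

Behavioral outcomes are binary: for WS analyses the eligible trials are
wins and the outcome is stay-on-next-trial; for LS analyses the eligible
trials are losses and the outcome is shift.  Per-rat binomial logistic
regressions relate the z-scored latent predictor to these outcomes;
z-scoring is per rat over the fitting subset, so the betas are invariant to
affine rescaling of the raw predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .behavior import transition_pairs
from .models import session_negloglik
from .task import drop_invalid, session_iter

__all__ = ["K_GRID", "KScanResult", "weighted_rpe_series", "k_grid_scan",
           "latent_traces", "logistic_latent_correlation",
           "median_split_interaction", "attach_rpe"]

K_GRID = tuple(np.round(np.arange(0.5, 1.0001, 0.025), 3))
BEHAVIORS = ("WS", "LS")


def weighted_rpe_series(rpe, k: float) -> np.ndarray:
    """Two-trial weighted RPE, ``k*RPE_t + (1-k)*RPE_{t-1}``.

    The first entry (no predecessor within the session) is NaN and is
    dropped from every regression.
    """
    if not 0.5 <= k <= 1.0:
        raise ValueError("k must lie in [0.5, 1]")
    rpe = np.asarray(rpe, dtype=float)
    out = np.full(rpe.shape, np.nan)
    if rpe.size > 1:
        out[1:] = k * rpe[1:] + (1.0 - k) * rpe[:-1]
    return out


def _fit_logistic(y: np.ndarray, z: np.ndarray):
    """Univariate logistic regression of y on z (plus intercept).

    Returns (beta, penalized_flag).  On separation or non-convergence the
    fit falls back to an L2-penalized estimate.
    """
    X = sm.add_constant(z)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) \
                    and np.all(np.abs(res.params) < 50):
                return float(res.params[1]), False
        except Exception:
            pass
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-3, L1_wt=0.0)
    return float(res.params[1]), True


def _eligible_outcomes(trials: pd.DataFrame, behavior: str) -> pd.DataFrame:
    """Consecutive-trial pairs eligible for one behavior, with the binary
    outcome column ``y`` (stay after a win for WS; shift after a loss for
    LS) defined on the *next* trial."""
    if behavior not in BEHAVIORS:
        raise ValueError(f"behavior must be one of {BEHAVIORS}")
    pairs = transition_pairs(trials)
    if behavior == "WS":
        pairs = pairs[pairs["reward"] == 1].copy()
        pairs["y"] = pairs["stay"].astype(int)
    else:
        pairs = pairs[pairs["reward"] == 0].copy()
        pairs["y"] = (~pairs["stay"]).astype(int)
    return pairs


def attach_rpe(trials: pd.DataFrame, standard_fits: pd.DataFrame,
               ) -> pd.DataFrame:
    """Valid trials with an ``rpe`` column from the fitted standard model.

    ``standard_fits`` is the per-session fit table from
    :func:`dynaprl.fitting.fit_sessions` for the standard model (one row per
    (rat_id, session_id) with alpha/beta columns).
    """
    lookup = standard_fits.set_index(["rat_id", "session_id"])
    df = drop_invalid(trials).sort_values(
        ["rat_id", "session_id", "trial_index"], kind="stable")
    out = []
    for (rat, sess), grp in session_iter(df):
        row = lookup.loc[(rat, sess)]
        _, trace = session_negloglik(
            "standard", {"alpha": row["alpha"], "beta": row["beta"]}, grp)
        g = grp.copy()
        g["rpe"] = trace["rpe"].to_numpy()
        g["is_session_first"] = np.arange(len(g)) == 0
        out.append(g)
    return pd.concat(out, ignore_index=True)


@dataclass
class KScanResult:
    """Result of the weighted-RPE grid scan for one behavior."""

    behavior: str
    k_grid: tuple
    betas: pd.DataFrame          # rats x k, logistic weight on z-scored wRPE
    best_k: pd.Series            # per rat; |beta| maximised, ties -> larger k
    mean_curve: pd.Series        # group-mean beta per k
    penalized: pd.DataFrame = field(default=None)


def k_grid_scan(trials_with_rpe: pd.DataFrame, behavior: str = "WS",
                outcomes: pd.DataFrame | None = None) -> KScanResult:
    """Scan k over the grid, fitting one logistic regression per rat per k.

    ``trials_with_rpe`` is the output of :func:`attach_rpe`.  ``outcomes``
    may supply pre-computed eligible pairs with a custom binary ``y``
    column (used by the generative recovery checks); by default they are
    derived from the observed stay/shift behavior.
    """
    df = trials_with_rpe
    if outcomes is None:
        outcomes = _eligible_outcomes(df, behavior)
    # previous-trial RPE aligned within session
    srt = drop_invalid(df).sort_values(
        ["rat_id", "session_id", "trial_index"], kind="stable").copy()
    same = ((srt["rat_id"] == srt["rat_id"].shift())
            & (srt["session_id"] == srt["session_id"].shift()))
    srt["rpe_prev"] = srt["rpe"].shift()
    srt.loc[~same, "rpe_prev"] = np.nan
    key = ["rat_id", "session_id", "trial_index"]
    outcomes = outcomes.drop(columns=["rpe_cur", "rpe_prev"],
                             errors="ignore")
    merged = outcomes.merge(srt[key + ["rpe", "rpe_prev"]].rename(
        columns={"rpe": "rpe_cur"}), on=key, how="left")
    merged = merged.dropna(subset=["rpe_cur", "rpe_prev"])

    rats = sorted(merged["rat_id"].unique())
    betas = pd.DataFrame(index=rats, columns=list(K_GRID), dtype=float)
    pen = pd.DataFrame(False, index=rats, columns=list(K_GRID))
    for rat in rats:
        sub = merged[merged["rat_id"] == rat]
        y = sub["y"].to_numpy()
        for k in K_GRID:
            w = k * sub["rpe_cur"].to_numpy() \
                + (1 - k) * sub["rpe_prev"].to_numpy()
            sd = w.std()
            if sd == 0 or len(np.unique(y)) < 2:
                betas.loc[rat, k] = 0.0
                continue
            z = (w - w.mean()) / sd
            b, p = _fit_logistic(y, z)
            betas.loc[rat, k] = b
            pen.loc[rat, k] = p

    def _best(row):
        a = row.to_numpy(dtype=float)
        m = np.nanmax(np.abs(a))
        tied = [k for k, v in zip(K_GRID, a) if np.abs(v) == m]
        return max(tied)

    best_k = betas.apply(_best, axis=1)
    mean_curve = betas.mean(axis=0)
    return KScanResult(behavior=behavior, k_grid=K_GRID, betas=betas,
                       best_k=best_k, mean_curve=mean_curve, penalized=pen)


def latent_traces(trials: pd.DataFrame, avg_rpe_fits: pd.DataFrame,
                  grs_fits: pd.DataFrame) -> pd.DataFrame:
    """Valid trials with ``abs_avg_rpe`` and ``grs`` columns obtained by
    replaying each session through its fitted avgRPE and GRS models.

    ``avg_rpe_fits`` / ``grs_fits`` are per-session fit tables from
    :func:`dynaprl.fitting.fit_sessions`.  The GRS value is the reward
    trace of the fitted GRS model.
    """
    avg_lu = avg_rpe_fits.set_index(["rat_id", "session_id"])
    grs_lu = grs_fits.set_index(["rat_id", "session_id"])
    df = drop_invalid(trials)
    out = []
    for (rat, sess), grp in session_iter(df):
        try:
            arow = avg_lu.loc[(rat, sess)]
            grow = grs_lu.loc[(rat, sess)]
        except KeyError:
            raise ValueError(f"no fit for session {(rat, sess)!r}") from None
        _, atrace = session_negloglik(
            "avg_rpe", {"alpha": arow["alpha"], "beta": arow["beta"],
                        "hw": arow["hw"]}, grp)
        _, gtrace = session_negloglik(
            "grs", {"alpha": grow["alpha"], "beta": grow["beta"],
                    "alpha_r": grow["alpha_r"], "w_r": grow["w_r"]}, grp)
        g = grp.copy()
        g["abs_avg_rpe"] = np.abs(atrace["avg_rpe"].to_numpy())
        g["grs"] = gtrace["rtrace"].to_numpy()
        out.append(g)
    return pd.concat(out, ignore_index=True)


def _apply_subset(pairs: pd.DataFrame, subset: Mapping | None) -> pd.DataFrame:
    subset = subset or {}
    sel = pd.Series(True, index=pairs.index)
    if "contrast" in subset:
        sel &= pairs["contrast_label"] == subset["contrast"]
    if "phase" in subset:
        sel &= pairs["phase"] == subset["phase"]
    if "action_type" in subset:
        sel &= pairs["action_type"] == subset["action_type"]
    return pairs[sel]


def logistic_latent_correlation(trials_with_traces: pd.DataFrame,
                                behavior: str, predictor: str,
                                subset: Mapping | None = None,
                                outcomes: pd.DataFrame | None = None,
                                ) -> pd.DataFrame:
    """Per-rat logistic regression of a WS/LS outcome on a z-scored latent
    predictor (``abs_avg_rpe`` or ``grs``) within a trial subset.

    ``subset`` may restrict contrast, phase and action_type (e.g. the
    better-action late-phase trials of HC blocks).  Returns one row per rat
    with the regression weight, the trial count and flags; rats whose subset
    is empty or whose predictor is constant are flagged, not dropped.
    """
    if predictor not in ("abs_avg_rpe", "grs"):
        raise ValueError("predictor must be 'abs_avg_rpe' or 'grs'")
    pairs = outcomes if outcomes is not None \
        else _eligible_outcomes(trials_with_traces, behavior)
    pairs = _apply_subset(pairs, subset)
    rows = []
    for rat in sorted(trials_with_traces["rat_id"].unique()):
        sub = pairs[pairs["rat_id"] == rat]
        x = sub[predictor].to_numpy(dtype=float)
        y = sub["y"].to_numpy()
        row = {"rat_id": rat, "behavior": behavior, "predictor": predictor,
               "n": len(sub), "beta": np.nan, "penalized": False,
               "defined": False}
        if len(sub) >= 5 and x.std() > 0 and len(np.unique(y)) == 2:
            z = (x - x.mean()) / x.std()
            b, p = _fit_logistic(y, z)
            row.update(beta=b, penalized=p, defined=True)
        rows.append(row)
    return pd.DataFrame(rows)


def median_split_interaction(trials_with_traces: pd.DataFrame,
                             subset: Mapping | None = None,
                             behavior: str = "WS",
                             contrasts: tuple = ("HC", "LC"),
                             outcomes: pd.DataFrame | None = None,
                             ) -> pd.DataFrame:
    """WS probability in the 2x2 split of GRS x |avgRPE| states.

    Per rat and contrast, the eligible trials (wins for WS, losses for LS,
    within ``subset``) are split at the rat-by-contrast medians of GRS and
    |avgRPE| (ties to the low side) and the stay/shift probability is
    computed per cell with counts.  Cells with zero denominator are flagged.
    ``outcomes`` may inject pre-computed eligible pairs with a custom binary
    ``y`` (generative calibration checks).
    """
    pairs = outcomes if outcomes is not None \
        else _eligible_outcomes(trials_with_traces, behavior)
    pairs = _apply_subset(pairs, subset)
    rows = []
    for rat in sorted(trials_with_traces["rat_id"].unique()):
        for contrast in contrasts:
            sub = pairs[(pairs["rat_id"] == rat)
                        & (pairs["contrast_label"] == contrast)]
            if len(sub) == 0:
                for cell in ("hi/hi", "hi/lo", "lo/hi", "lo/lo"):
                    rows.append({"rat_id": rat, "contrast": contrast,
                                 "cell": cell, "numerator": 0,
                                 "denominator": 0, "probability": np.nan,
                                 "defined": False})
                continue
            g = sub["grs"].to_numpy(dtype=float)
            a = sub["abs_avg_rpe"].to_numpy(dtype=float)
            hi_g = g > np.median(g)
            hi_a = a > np.median(a)
            y = sub["y"].to_numpy()
            for cell, mask in (("hi/hi", hi_g & hi_a),
                               ("hi/lo", hi_g & ~hi_a),
                               ("lo/hi", ~hi_g & hi_a),
                               ("lo/lo", ~hi_g & ~hi_a)):
                d = int(mask.sum())
                n = int(y[mask].sum())
                rows.append({"rat_id": rat, "contrast": contrast,
                             "cell": cell, "numerator": n, "denominator": d,
                             "probability": n / d if d else np.nan,
                             "defined": d > 0})
    return pd.DataFrame(rows)
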