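"""Group-level statistics: standardized effect sizes and the
random-intercept linear model used to compare per-rat measurements.

The mixed model delegates to statsmodels' ``MixedLM`` (rat as random
intercept); this module specifies the contract — per-term tests,
Tukey-adjusted pairwise contrasts and effect sizes — not the solver.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = ["cohens_d", "partial_eta_squared", "mixed_anova"]


def cohens_d(x, y) -> float:
    """Cohen's d, ``(mean(x) - mean(y)) / pooled SD`` with (n-1)-weighted
    pooling.  Positive when the first sample's mean is larger."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                     / (nx + ny - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / pooled)


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """``SS_effect / (SS_effect + SS_error)``."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be nonnegative")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("both sums of squares are zero")
    return float(ss_effect / (ss_effect + ss_error))


def _tukey_p(t_stat: float, k: int, df: float) -> float:
    """Tukey HSD p-value from the studentized range distribution."""
    if k < 2 or df <= 0:
        return np.nan
    q = abs(t_stat) * np.sqrt(2.0)
    return float(sps.studentized_range.sf(q, k, df))


def mixed_anova(data: pd.DataFrame, dv: str, factors: Sequence[str],
                rat: str = "rat_id", interactions: bool = True) -> dict:
    """Random-intercept linear model of ``dv`` on categorical ``factors``.

    Fits ``dv ~ C(f1) * C(f2) ...`` with a per-rat random intercept and
    returns

    * ``anova``: one row per model term with a Wald F statistic (chi-square
      divided by its degrees of freedom), numerator/denominator df, p-value,
      and an F-based partial-eta-squared approximation
      ``F*df1 / (F*df1 + df2)``;
    * ``pairwise``: Tukey-adjusted contrasts between the levels of each
      factor (marginal means over the other factors) with Cohen's d on the
      per-observation residual scale.

    Requires >= 2 rats and >= 2 levels per factor.  A rank-deficient design
    raises with an explicit message.
    """
    if data[rat].nunique() < 2:
        raise ValueError("mixed model needs at least two rats")
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least two levels")
    op = " * " if interactions else " + "
    formula = f"{dv} ~ " + op.join(f"C({f})" for f in factors)
    model = smf.mixedlm(formula, data=data, groups=data[rat])
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("rank-deficient fixed-effects design")
    res = model.fit(reml=True)

    design_info = model.data.design_info
    params = res.fe_params.to_numpy()
    cov = res.cov_params().to_numpy()[:len(params), :len(params)]
    n_obs = len(data)
    df_resid = n_obs - len(params)

    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(len(params))[sl]
        b = params[idx]
        C = cov[np.ix_(idx, idx)]
        chi2 = float(b @ np.linalg.solve(C, b))
        df1 = len(idx)
        F = chi2 / df1
        p = float(sps.f.sf(F, df1, df_resid))
        pes = F * df1 / (F * df1 + df_resid)
        rows.append({"term": term, "F": F, "df_num": df1,
                     "df_den": df_resid, "p": p, "partial_eta_sq": pes})
    anova = pd.DataFrame(rows)

    pw_rows = []
    resid_sd = float(np.sqrt(res.scale))
    for f in factors:
        levels = sorted(data[f].astype(str).unique())
        k = len(levels)
        for a, b_lvl in itertools.combinations(levels, 2):
            # marginal means: average model prediction over the observed
            # design within each level
            preds = {}
            for lvl in (a, b_lvl):
                d = data.copy()
                d[f] = lvl
                exog = np.asarray(patsy.dmatrix(design_info, d))
                w = exog.mean(axis=0)
                preds[lvl] = (float(w @ params), w)
            diff = preds[a][0] - preds[b_lvl][0]
            wdiff = preds[a][1] - preds[b_lvl][1]
            se = float(np.sqrt(wdiff @ cov @ wdiff))
            t = diff / se if se > 0 else np.nan
            p_unadj = float(2 * sps.t.sf(abs(t), df_resid))
            p_tukey = _tukey_p(t, k, df_resid)
            pw_rows.append({"factor": f, "level_a": a, "level_b": b_lvl,
                            "estimate": diff, "se": se, "t": t,
                            "p_unadjusted": p_unadj,
                            "p_tukey": max(p_tukey, p_unadj)
                            if np.isfinite(p_tukey) else np.nan,
                            "cohens_d": diff / resid_sd if resid_sd > 0
                            else np.nan})
    return {"anova": anova, "pairwise": pd.DataFrame(pw_rows),
            "result": res}
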