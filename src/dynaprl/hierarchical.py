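"""Hierarchical two-group Bayesian estimation of RL-model parameters.

Each rat ``r`` in group ``g`` has an unconstrained parameter vector
``theta_r`` whose components are Normally distributed around group means:

    theta_{r,p} ~ Normal(mu_p + s_g * delta_p, sigma_p**2)

with ``s_g = +1/2`` for the first group label and ``-1/2`` for the second,
so ``delta_p > 0`` means the first group has the larger value of parameter
``p``.  Unconstrained components map to the native bounded scale through a
scaled logistic link (log link for the inverse temperature).  Hyperpriors:
``mu_p ~ Normal(0, 1.5)``, ``delta_p ~ Normal(0, 1)``,
``sigma_p ~ HalfNormal(1)``.  A rat's likelihood is the product of its
session likelihoods with a single parameter set per rat (sessions can
alternatively be treated as the exchangeable unit via ``unit="session"``).

Posterior sampling uses Metropolis-within-Gibbs: adaptive random-walk
Metropolis on each rat-level component, exact conjugate Normal draws for
``(mu_p, delta_p)``, and univariate slice sampling for ``sigma_p``.  To
avoid the slow hyperparameter mixing of a purely centered parameterization
(the usual funnel), each sweep interweaves non-centered moves that shift or
rescale a hyperparameter together with all rat-level values, accepted
against the data likelihood (ancillarity-sufficiency interweaving).
Convergence is monitored with the split-chain R-hat statistic over the
hyperparameters (threshold 1.05).

Group differences are summarised by the directed Bayes factor: the ratio of
posterior samples of ``delta_p`` above zero to those below zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .fitting import _nll_fn
from .models import get_model, _session_arrays
from .task import session_iter

__all__ = ["GroupPosterior", "directed_bayes_factor",
           "fit_hierarchical_groups"]

_MU_SD = 1.5
_DELTA_SD = 1.0
_RHAT_THRESHOLD = 1.05


def directed_bayes_factor(delta_samples) -> float:
    """Ratio of posterior samples of the group difference above zero to
    those below zero.  Exact zeros are excluded; if no sample falls on one
    side, the ratio is capped at the total number of (nonzero) samples."""
    d = np.asarray(delta_samples, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty delta sample")
    n_pos = int((d > 0).sum())
    n_neg = int((d < 0).sum())
    n = n_pos + n_neg
    if n == 0:
        raise ValueError("all delta samples are exactly zero")
    if n_neg == 0 or n_pos == 0:
        return float(n)
    return n_pos / n_neg


def _links(spec):
    """(forward, inverse) link per parameter: unconstrained -> native."""
    fwd, inv = [], []
    for name, (lo, hi) in zip(spec.param_names, spec.bounds):
        if name == "beta":
            fwd.append(np.exp)
            inv.append(np.log)
        elif name == "phi":
            fwd.append(lambda x: x)
            inv.append(lambda x: x)
        else:
            span = hi - lo
            fwd.append(lambda x, lo=lo, span=span: lo + span * expit(x))
            inv.append(lambda x, lo=lo, span=span: logit((x - lo) / span))
    return fwd, inv


def _slice_sample_log_sigma(u0: float, resid_ss: float, n: int,
                            rng: np.random.Generator) -> float:
    """Slice sample u = log(sigma) given residual sum of squares."""

    def logp(u):
        s2 = np.exp(2.0 * u)
        return -n * u - resid_ss / (2.0 * s2) - s2 / 2.0 + u

    y = logp(u0) + np.log(rng.random())
    w = 1.0
    lo = u0 - w * rng.random()
    hi = lo + w
    for _ in range(20):
        if logp(lo) <= y:
            break
        lo -= w
    for _ in range(20):
        if logp(hi) <= y:
            break
        hi += w
    for _ in range(100):
        u1 = rng.uniform(lo, hi)
        if logp(u1) >= y:
            return u1
        if u1 < u0:
            lo = u1
        else:
            hi = u1
    return u0


@dataclass
class GroupPosterior:
    """Posterior summary of the hierarchical two-group fit."""

    model: str
    group_labels: tuple
    param_names: tuple
    mu: dict          # param -> (chains, draws) array, unconstrained scale
    delta: dict       # param -> (chains, draws)
    sigma: dict       # param -> (chains, draws)
    rat_params: pd.DataFrame  # posterior mean per rat, native scale
    dbf: dict = field(default_factory=dict)
    rhat: dict = field(default_factory=dict)
    converged: bool = False

    def delta_flat(self, param: str) -> np.ndarray:
        return np.asarray(self.delta[param]).ravel()

    def prob_delta_positive(self, param: str) -> float:
        d = self.delta_flat(param)
        return float((d > 0).mean())


def _collect_units(trials: pd.DataFrame, groups: Mapping[str, str],
                   unit: str):
    """Group trials into exchangeable units with their group labels and
    per-session (choices, rewards) arrays."""
    units: dict[str, list] = {}
    labels: dict[str, str] = {}
    for (rat, sess), grp in session_iter(trials):
        if rat not in groups:
            raise ValueError(f"rat {rat!r} has no group assignment")
        uid = rat if unit == "rat" else f"{rat}::{sess}"
        units.setdefault(uid, []).append(_session_arrays(grp))
        labels[uid] = groups[rat]
    return units, labels


def fit_hierarchical_groups(trials: pd.DataFrame, groups: Mapping[str, str],
                            model: str = "asym",
                            group_labels: Sequence[str] | None = None,
                            chains: int = 2, warmup: int = 500,
                            draws: int = 1000, seed: int | None = None,
                            unit: str = "rat",
                            init_restarts: int = 4) -> GroupPosterior:
    """Fit the hierarchical two-group model by MCMC.

    Parameters
    ----------
    trials:
        Trial table covering every rat's sessions.
    groups:
        Mapping rat_id -> group label; exactly two labels must occur.
    group_labels:
        Order of the two labels; ``delta > 0`` means the *first* label has
        the larger parameter.  Defaults to sorted order.
    unit:
        ``"rat"`` (one parameter set per rat, the default) or ``"session"``
        (every session exchangeable, inheriting its rat's group).
    """
    if unit not in ("rat", "session"):
        raise ValueError("unit must be 'rat' or 'session'")
    spec = get_model(model)
    units, labels = _collect_units(trials, groups, unit)
    found = sorted(set(labels.values()))
    if group_labels is None:
        group_labels = found
    group_labels = tuple(group_labels)
    if len(group_labels) != 2 or set(found) != set(group_labels):
        raise ValueError(
            f"exactly two groups required; found {found}, asked {group_labels}")
    unit_ids = sorted(units)
    if len(unit_ids) < 2:
        raise ValueError("need at least two exchangeable units")
    signs = np.array([0.5 if labels[u] == group_labels[0] else -0.5
                      for u in unit_ids])
    if not ((signs > 0).any() and (signs < 0).any()):
        raise ValueError("one of the groups is empty")

    n_units, n_par = len(unit_ids), spec.n_params
    fwd, inv = _links(spec)
    bounds = list(spec.bounds)
    # vectorised unconstrained -> native map (hot path)
    is_exp = np.array([n == "beta" for n in spec.param_names])
    is_id = np.array([n == "phi" for n in spec.param_names])
    lo_arr = np.array([b[0] for b in bounds])
    span_arr = np.array([b[1] - b[0] for b in bounds])

    # per-unit likelihood closures
    unit_fns = []
    for u in unit_ids:
        fns = [_nll_fn(model, ch, rw) for ch, rw in units[u]]
        unit_fns.append(fns)

    def unit_nll(i: int, native: np.ndarray) -> float:
        return float(sum(fn(native) for fn in unit_fns[i]))

    def to_native(th: np.ndarray) -> np.ndarray:
        nat = lo_arr + span_arr * expit(th)
        if is_exp.any():
            # clip to keep exp finite; beta ~ 2.2e4 is far past saturation
            nat[is_exp] = np.exp(np.minimum(th[is_exp], 10.0))
        if is_id.any():
            nat[is_id] = th[is_id]
        return nat

    # --- initialisation: per-unit MLE, transformed to the unconstrained scale
    rng0 = np.random.default_rng(seed)
    theta0 = np.empty((n_units, n_par))
    from scipy.optimize import minimize
    for i in range(n_units):
        best_x, best_f = None, np.inf
        obj = lambda x: sum(fn(x) for fn in unit_fns[i])
        for _ in range(init_restarts):
            x0 = np.array([rng0.uniform(lo, hi) for lo, hi in bounds])
            res = minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                           options={"ftol": 1e-9, "maxiter": 300})
            if res.fun < best_f:
                best_f, best_x = float(res.fun), res.x
        x = best_x.copy()
        for p, (lo, hi) in enumerate(bounds):
            eps = 1e-3 * (hi - lo)
            x[p] = np.clip(x[p], lo + eps, hi - eps)
        theta0[i] = [inv[p](x[p]) for p in range(n_par)]

    def run_chain(chain_seed: int):
        rng = np.random.default_rng(chain_seed)
        theta = theta0 + 0.05 * rng.standard_normal(theta0.shape)
        mu = theta.mean(axis=0)
        delta = np.zeros(n_par)
        sigma = np.clip(theta.std(axis=0), 0.2, 2.0)
        cur_nll = np.array([unit_nll(i, to_native(theta[i]))
                            for i in range(n_units)])
        scales = np.full((n_units, n_par), 0.25)
        acc = np.zeros((n_units, n_par))
        tries = np.zeros((n_units, n_par))
        # non-centered interweaving moves: (translate mu, translate delta,
        # rescale sigma) per parameter
        asis_scales = np.full((3, n_par), 0.2)
        asis_acc = np.zeros((3, n_par))
        asis_tries = np.zeros((3, n_par))

        def _try_joint(p, nll_new_fn, log_prior_diff, move):
            """Accept/reject a joint hyper + rat-level move for parameter p."""
            nll_new = np.array([nll_new_fn(i) for i in range(n_units)])
            log_r = (cur_nll.sum() - nll_new.sum()) + log_prior_diff
            asis_tries[move, p] += 1
            if np.log(rng.random()) < log_r:
                asis_acc[move, p] += 1
                return nll_new, True
            return None, False

        mu_out = np.empty((draws, n_par))
        delta_out = np.empty((draws, n_par))
        sigma_out = np.empty((draws, n_par))
        native_sum = np.zeros((n_units, n_par))

        for it in range(warmup + draws):
            means = mu[None, :] + signs[:, None] * delta[None, :]
            # unit-level adaptive random-walk Metropolis, one component at a time
            for i in range(n_units):
                for p in range(n_par):
                    prop = theta[i].copy()
                    prop[p] += scales[i, p] * rng.standard_normal()
                    nll_new = unit_nll(i, to_native(prop))
                    d_prior = ((theta[i, p] - means[i, p]) ** 2
                               - (prop[p] - means[i, p]) ** 2) / (2 * sigma[p] ** 2)
                    log_r = (cur_nll[i] - nll_new) + d_prior
                    tries[i, p] += 1
                    if np.log(rng.random()) < log_r:
                        theta[i] = prop
                        cur_nll[i] = nll_new
                        acc[i, p] += 1
            if it < warmup and (it + 1) % 50 == 0:
                rate = acc / np.maximum(tries, 1)
                scales *= np.exp(1.5 * (rate - 0.44))
                np.clip(scales, 1e-3, 5.0, out=scales)
                acc[:] = 0
                tries[:] = 0
                arate = asis_acc / np.maximum(asis_tries, 1)
                asis_scales *= np.exp(1.5 * (arate - 0.3))
                np.clip(asis_scales, 1e-3, 5.0, out=asis_scales)
                asis_acc[:] = 0
                asis_tries[:] = 0

            # conjugate (mu, delta) draw per parameter
            for p in range(n_par):
                y = theta[:, p]
                s2 = sigma[p] ** 2
                xtx = np.array([[n_units, signs.sum()],
                                [signs.sum(), (signs ** 2).sum()]]) / s2
                prec = xtx + np.diag([1 / _MU_SD ** 2, 1 / _DELTA_SD ** 2])
                xty = np.array([y.sum(), (signs * y).sum()]) / s2
                cov = np.linalg.inv(prec)
                mean = cov @ xty
                draw = rng.multivariate_normal(mean, cov)
                mu[p], delta[p] = draw
                resid = y - (mu[p] + signs * delta[p])
                u = _slice_sample_log_sigma(np.log(sigma[p]),
                                            float(resid @ resid),
                                            n_units, rng)
                sigma[p] = np.exp(u)

                if it % 2 == 0:
                    continue

                def _nll_col(col):
                    def fn(i):
                        th = theta[i].copy()
                        th[p] = col[i]
                        return unit_nll(i, to_native(th))
                    return fn

                # interweaving: translate mu with all rat values
                t = asis_scales[0, p] * rng.standard_normal()
                col = theta[:, p] + t
                dp = (mu[p] ** 2 - (mu[p] + t) ** 2) / (2 * _MU_SD ** 2)
                nll_new, ok = _try_joint(p, _nll_col(col), dp, 0)
                if ok:
                    theta[:, p] = col
                    mu[p] += t
                    cur_nll[:] = nll_new
                # translate delta with group-signed rat values
                d = asis_scales[1, p] * rng.standard_normal()
                col = theta[:, p] + signs * d
                dp = (delta[p] ** 2 - (delta[p] + d) ** 2) / (2 * _DELTA_SD ** 2)
                nll_new, ok = _try_joint(p, _nll_col(col), dp, 1)
                if ok:
                    theta[:, p] = col
                    delta[p] += d
                    cur_nll[:] = nll_new
                # rescale sigma with centered residuals
                e = asis_scales[2, p] * rng.standard_normal()
                m_p = mu[p] + signs * delta[p]
                col = m_p + np.exp(e) * (theta[:, p] - m_p)
                s_new = sigma[p] * np.exp(e)
                dp = (sigma[p] ** 2 - s_new ** 2) / 2.0 + e
                nll_new, ok = _try_joint(p, _nll_col(col), dp, 2)
                if ok:
                    theta[:, p] = col
                    sigma[p] = s_new
                    cur_nll[:] = nll_new

            if it >= warmup:
                j = it - warmup
                mu_out[j] = mu
                delta_out[j] = delta
                sigma_out[j] = sigma
                for i in range(n_units):
                    native_sum[i] += to_native(theta[i])
        return mu_out, delta_out, sigma_out, native_sum / draws

    master = np.random.default_rng(seed)
    chain_seeds = master.integers(2 ** 31, size=chains)
    results = [run_chain(int(s)) for s in chain_seeds]

    mu_s = {p: np.stack([r[0][:, k] for r in results])
            for k, p in enumerate(spec.param_names)}
    delta_s = {p: np.stack([r[1][:, k] for r in results])
               for k, p in enumerate(spec.param_names)}
    sigma_s = {p: np.stack([r[2][:, k] for r in results])
               for k, p in enumerate(spec.param_names)}
    native_mean = np.mean([r[3] for r in results], axis=0)
    rat_params = pd.DataFrame(native_mean, columns=list(spec.param_names))
    rat_params.insert(0, "unit", unit_ids)
    rat_params.insert(1, "group", [labels[u] for u in unit_ids])

    rhat = {}
    for p in spec.param_names:
        vals = []
        for samp in (mu_s[p], delta_s[p], sigma_s[p]):
            if chains > 1:
                vals.append(float(az.rhat(az.convert_to_dataset(samp))["x"]))
        rhat[p] = max(vals) if vals else np.nan
    converged = bool(chains > 1
                     and all(np.isfinite(v) and v < _RHAT_THRESHOLD
                             for v in rhat.values()))
    dbf = {p: directed_bayes_factor(delta_s[p]) for p in spec.param_names}

    return GroupPosterior(model=model, group_labels=group_labels,
                          param_names=spec.param_names, mu=mu_s,
                          delta=delta_s, sigma=sigma_s,
                          rat_params=rat_params, dbf=dbf, rhat=rhat,
                          converged=converged)
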