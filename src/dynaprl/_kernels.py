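"""Numba-compiled likelihood kernels for the trial-by-trial RL models.

Each kernel walks a session once, in trial order, applying the model's update
rule and accumulating the negative log-likelihood of the observed choices
under a two-action softmax.  Choices are coded 0/1 (left/right), rewards 0/1.
Values start at zero for both actions at the start of every session.

Log choice probabilities are floored at log(1e-12) so that extreme inverse
temperatures cannot produce -inf.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG_FLOOR = np.log(1e-12)


@njit(cache=True)
def _log_sigmoid(x: float) -> float:
    # log(1 / (1 + exp(-x))), stable for large |x|
    if x >= 0.0:
        return -np.log1p(np.exp(-x))
    return x - np.log1p(np.exp(x))


@njit(cache=True)
def _logp_choice(v_chosen: float, v_other: float, beta: float, hist: float) -> float:
    lp = _log_sigmoid(beta * (v_chosen - v_other) + hist)
    if lp < LOG_FLOOR:
        lp = LOG_FLOOR
    return lp


@njit(cache=True)
def nll_standard_trace(choices, rewards, alpha, beta):
    n = choices.shape[0]
    v = np.zeros(2)
    v0 = np.empty(n)
    v1 = np.empty(n)
    rpe = np.empty(n)
    p = np.empty(n)
    nll = 0.0
    for t in range(n):
        c = choices[t]
        v0[t] = v[0]
        v1[t] = v[1]
        lp = _logp_choice(v[c], v[1 - c], beta, 0.0)
        p[t] = np.exp(lp)
        nll -= lp
        rpe[t] = rewards[t] - v[c]
        v[c] += alpha * rpe[t]
    return nll, v0, v1, rpe, p


@njit(cache=True)
def nll_standard(choices, rewards, alpha, beta):
    n = choices.shape[0]
    v = np.zeros(2)
    nll = 0.0
    for t in range(n):
        c = choices[t]
        nll -= _logp_choice(v[c], v[1 - c], beta, 0.0)
        v[c] += alpha * (rewards[t] - v[c])
    return nll


@njit(cache=True)
def nll_avg_rpe_trace(choices, rewards, alpha, beta, hw):
    n = choices.shape[0]
    v = np.zeros(2)
    v0 = np.empty(n)
    v1 = np.empty(n)
    rpe = np.empty(n)
    avg = np.empty(n)
    p = np.empty(n)
    prev_avg = 0.0
    nll = 0.0
    for t in range(n):
        c = choices[t]
        v0[t] = v[0]
        v1[t] = v[1]
        lp = _logp_choice(v[c], v[1 - c], beta, 0.0)
        p[t] = np.exp(lp)
        nll -= lp
        rpe[t] = rewards[t] - v[c]
        prev_avg = alpha * rpe[t] + hw * prev_avg
        avg[t] = prev_avg
        v[c] += prev_avg
    return nll, v0, v1, rpe, avg, p


@njit(cache=True)
def nll_avg_rpe(choices, rewards, alpha, beta, hw):
    n = choices.shape[0]
    v = np.zeros(2)
    prev_avg = 0.0
    nll = 0.0
    for t in range(n):
        c = choices[t]
        nll -= _logp_choice(v[c], v[1 - c], beta, 0.0)
        prev_avg = alpha * (rewards[t] - v[c]) + hw * prev_avg
        v[c] += prev_avg
    return nll


@njit(cache=True)
def nll_grs_trace(choices, rewards, alpha, beta, alpha_r, w_r):
    n = choices.shape[0]
    v = np.zeros(2)
    v0 = np.empty(n)
    v1 = np.empty(n)
    rpe = np.empty(n)
    rtrace = np.empty(n)
    p = np.empty(n)
    rt = 0.0
    nll = 0.0
    for t in range(n):
        c = choices[t]
        if t > 0:
            rt = rt + (rewards[t - 1] - rt) * alpha_r
        rtrace[t] = rt
        v0[t] = v[0]
        v1[t] = v[1]
        lp = _logp_choice(v[c], v[1 - c], beta, 0.0)
        p[t] = np.exp(lp)
        nll -= lp
        rpe[t] = rewards[t] + w_r * rt - v[c]
        v[c] += alpha * rpe[t]
    return nll, v0, v1, rpe, rtrace, p


@njit(cache=True)
def nll_grs(choices, rewards, alpha, beta, alpha_r, w_r):
    n = choices.shape[0]
    v = np.zeros(2)
    rt = 0.0
    nll = 0.0
    for t in range(n):
        c = choices[t]
        if t > 0:
            rt = rt + (rewards[t - 1] - rt) * alpha_r
        nll -= _logp_choice(v[c], v[1 - c], beta, 0.0)
        v[c] += alpha * (rewards[t] + w_r * rt - v[c])
    return nll


@njit(cache=True)
def nll_asym_trace(choices, rewards, alpha_pos, alpha_neg, gamma_pos, gamma_neg,
                   beta, phi, use_hist):
    n = choices.shape[0]
    v = np.zeros(2)
    v0 = np.empty(n)
    v1 = np.empty(n)
    rpe = np.empty(n)
    p = np.empty(n)
    prev = -1
    nll = 0.0
    for t in range(n):
        c = choices[t]
        v0[t] = v[0]
        v1[t] = v[1]
        hist = 0.0
        if use_hist and prev >= 0:
            hist = phi if c == prev else -phi
        lp = _logp_choice(v[c], v[1 - c], beta, hist)
        p[t] = np.exp(lp)
        nll -= lp
        rpe[t] = rewards[t] - v[c]
        if rewards[t] == 1:
            v[c] += alpha_pos * rpe[t]
            v[1 - c] *= gamma_pos
        else:
            v[c] += alpha_neg * rpe[t]
            v[1 - c] *= gamma_neg
        prev = c
    return nll, v0, v1, rpe, p


@njit(cache=True)
def nll_asym(choices, rewards, alpha_pos, alpha_neg, gamma_pos, gamma_neg,
             beta, phi, use_hist):
    n = choices.shape[0]
    v = np.zeros(2)
    prev = -1
    nll = 0.0
    for t in range(n):
        c = choices[t]
        hist = 0.0
        if use_hist and prev >= 0:
            hist = phi if c == prev else -phi
        nll -= _logp_choice(v[c], v[1 - c], beta, hist)
        if rewards[t] == 1:
            v[c] += alpha_pos * (rewards[t] - v[c])
            v[1 - c] *= gamma_pos
        else:
            v[c] += alpha_neg * (rewards[t] - v[c])
            v[1 - c] *= gamma_neg
        prev = c
    return nll
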