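"""Independent brute-force reference computations for the test suite.

Everything here is written in plain Python (lists, math) directly from the
model update rules, deliberately not sharing any code with the package, so
it can serve as an oracle for the vectorised/compiled implementations.
"""

import math

FLOOR = math.log(1e-12)


def _softmax_logp(v_c: float, v_u: float, beta: float, bonus_c: float = 0.0,
                  bonus_u: float = 0.0):
    x = beta * v_c + bonus_c
    y = beta * v_u + bonus_u
    m = max(x, y)
    lp = (x - m) - math.log(math.exp(x - m) + math.exp(y - m))
    return max(lp, FLOOR)


def nll_standard(choices, rewards, alpha, beta):
    v = [0.0, 0.0]
    nll = 0.0
    for c, r in zip(choices, rewards):
        nll -= _softmax_logp(v[c], v[1 - c], beta)
        v[c] = v[c] + alpha * (r - v[c])
    return nll


def nll_avg_rpe(choices, rewards, alpha, beta, hw):
    v = [0.0, 0.0]
    avg = 0.0
    nll = 0.0
    for c, r in zip(choices, rewards):
        nll -= _softmax_logp(v[c], v[1 - c], beta)
        rpe = r - v[c]
        avg = alpha * rpe + hw * avg
        v[c] = v[c] + avg
    return nll


def nll_grs(choices, rewards, alpha, beta, alpha_r, w_r):
    v = [0.0, 0.0]
    rtrace = 0.0
    prev_r = None
    nll = 0.0
    for c, r in zip(choices, rewards):
        if prev_r is not None:
            rtrace = rtrace + (prev_r - rtrace) * alpha_r
        nll -= _softmax_logp(v[c], v[1 - c], beta)
        rpe = r + w_r * rtrace - v[c]
        v[c] = v[c] + alpha * rpe
        prev_r = r
    return nll


def nll_asym(choices, rewards, ap, an, gp, gn, beta, phi=0.0, use_hist=False):
    v = [0.0, 0.0]
    prev = None
    nll = 0.0
    for c, r in zip(choices, rewards):
        bonus_c = bonus_u = 0.0
        if use_hist and prev is not None:
            # the stickiness bonus attaches to whichever action repeats the
            # previous choice
            if c == prev:
                bonus_c = phi
            else:
                bonus_u = phi
        nll -= _softmax_logp(v[c], v[1 - c], beta, bonus_c, bonus_u)
        if r == 1:
            v[c] = v[c] + ap * (r - v[c])
            v[1 - c] = v[1 - c] * gp
        else:
            v[c] = v[c] + an * (r - v[c])
            v[1 - c] = v[1 - c] * gn
        prev = c
    return nll


def session_nll(model, params, choices, rewards):
    """Dispatch by model identifier using the package's parameter names."""
    p = params
    if model == "standard":
        return nll_standard(choices, rewards, p["alpha"], p["beta"])
    if model == "avg_rpe":
        return nll_avg_rpe(choices, rewards, p["alpha"], p["beta"], p["hw"])
    if model == "grs":
        return nll_grs(choices, rewards, p["alpha"], p["beta"],
                       p["alpha_r"], p["w_r"])
    if model == "asym":
        return nll_asym(choices, rewards, p["alpha_pos"], p["alpha_neg"],
                        p["gamma_pos"], p["gamma_neg"], p["beta"])
    if model == "asym_ch":
        return nll_asym(choices, rewards, p["alpha_pos"], p["alpha_neg"],
                        p["gamma_pos"], p["gamma_neg"], p["beta"],
                        p["phi"], True)
    raise ValueError(model)


def ws_ls_counts(choices, rewards):
    """Hand-enumerated WS/LS numerators and denominators for one session."""
    ws = wins = ls = losses = 0
    for t in range(len(choices) - 1):
        if rewards[t] == 1:
            wins += 1
            if choices[t + 1] == choices[t]:
                ws += 1
        else:
            losses += 1
            if choices[t + 1] != choices[t]:
                ls += 1
    return ws, wins, ls, losses
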