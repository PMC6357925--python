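"""Numba kernels for the PVL likelihood recursion.

Single source of truth for the trial-by-trial recursion: the scalar API in
``pvl_model`` and both fitters in ``estimation`` all route through
:func:`loglik_seq` / :func:`loglik_batch`.

``theta_rule``: 0 = constant theta = 3**c - 1, 1 = trial-dependent (t/10)**c.
Per-trial choice probabilities are floored at 1e-12 inside the log so the
likelihood stays finite for in-range parameters.
"""

import numpy as np
from numba import njit

PROB_FLOOR = 1e-12

THETA_AS_PRINTED = 0
THETA_TRIAL_DEPENDENT = 1


@njit(cache=True)
def loglik_seq(decks, x, a, lam, A, c, theta_rule):
    """Log-likelihood of one choice sequence under the PVL model.

    decks: int array of chosen deck indices (0..3); x: net outcomes already
    multiplied by the payoff scale. Expectancies start at zero, so trial 1
    contributes log(1/4).
    """
    e0 = 0.0
    e1 = 0.0
    e2 = 0.0
    e3 = 0.0
    theta = 3.0 ** c - 1.0
    ll = 0.0
    n = decks.shape[0]
    for t in range(n):
        if theta_rule == THETA_TRIAL_DEPENDENT:
            theta = ((t + 1) / 10.0) ** c
        z0 = theta * e0
        z1 = theta * e1
        z2 = theta * e2
        z3 = theta * e3
        m = z0
        if z1 > m:
            m = z1
        if z2 > m:
            m = z2
        if z3 > m:
            m = z3
        w0 = np.exp(z0 - m)
        w1 = np.exp(z1 - m)
        w2 = np.exp(z2 - m)
        w3 = np.exp(z3 - m)
        denom = w0 + w1 + w2 + w3
        d = decks[t]
        if d == 0:
            p = w0 / denom
        elif d == 1:
            p = w1 / denom
        elif d == 2:
            p = w2 / denom
        else:
            p = w3 / denom
        if p < PROB_FLOOR:
            p = PROB_FLOOR
        ll += np.log(p)
        xt = x[t]
        if xt > 0.0:
            u = xt ** a
        elif xt == 0.0:
            u = 0.0
        else:
            u = -lam * (-xt) ** a
        e0 *= A
        e1 *= A
        e2 *= A
        e3 *= A
        if d == 0:
            e0 += u
        elif d == 1:
            e1 += u
        elif d == 2:
            e2 += u
        else:
            e3 += u
    return ll


@njit(cache=True)
def loglik_batch(decks2d, x2d, subj_idx, params, theta_rule):
    """Log-likelihoods for many (sequence, parameter) rows.

    Row r evaluates parameter vector params[r] = (a, lam, A, c) against
    sequence subj_idx[r] of the stacked (n_subjects, n_trials) arrays.
    """
    n = params.shape[0]
    out = np.empty(n)
    for r in range(n):
        s = subj_idx[r]
        out[r] = loglik_seq(
            decks2d[s], x2d[s], params[r, 0], params[r, 1], params[r, 2], params[r, 3], theta_rule
        )
    return out
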