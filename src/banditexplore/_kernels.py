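"""Compiled inner loops: per-trial likelihood recursions and the tied
explore/exploit HMM forward-backward / EM.

These kernels duplicate, in compiled form, the readable recursions in
:mod:`banditexplore.agents` and the log-space forward pass in
:mod:`banditexplore.hmm_explore`; the test suite asserts the two routes
agree to 1e-10. Choices are passed 0-based here.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG_FLOOR = -690.7755278982137  # log(1e-300)


@njit(cache=True)
def kalman_nll_kernel(
    choices, rewards, phi, omega, beta, lam, theta, obs_var, diff_var
):
    """Negative log-likelihood of a choice sequence under the Bayesian
    learner. Returns (nll, n_floored)."""
    mu = np.full(3, theta)
    var = np.full(3, diff_var / (1.0 - lam * lam))
    prev = -1
    nll = 0.0
    n_floored = 0
    for t in range(choices.shape[0]):
        d0 = mu[0] + phi * var[0]
        d1 = mu[1] + phi * var[1]
        d2 = mu[2] + phi * var[2]
        if prev == 0:
            d0 += omega
        elif prev == 1:
            d1 += omega
        elif prev == 2:
            d2 += omega
        x0, x1, x2 = beta * d0, beta * d1, beta * d2
        m = max(x0, max(x1, x2))
        lse = m + np.log(np.exp(x0 - m) + np.exp(x1 - m) + np.exp(x2 - m))
        c = choices[t]
        if c == 0:
            logp = x0 - lse
        elif c == 1:
            logp = x1 - lse
        else:
            logp = x2 - lse
        if logp < LOG_FLOOR:
            logp = LOG_FLOOR
            n_floored += 1
        nll -= logp
        # belief update with the observed choice and reward
        gain = var[c] / (var[c] + obs_var)
        mu[c] += gain * (rewards[t] - mu[c])
        var[c] *= 1.0 - gain
        for k in range(3):
            mu[k] = lam * mu[k] + (1.0 - lam) * theta
            var[k] = lam * lam * var[k] + diff_var
        prev = c
    return nll, n_floored


@njit(cache=True)
def rlck_nll_kernel(choices, rewards, alpha, alpha_c, tau, beta, gamma, labels):
    """Negative log-likelihood under the RL + choice-kernel learner.

    ``gamma < 0`` selects the plain RLCK model; otherwise the value
    learning rate is gamma * alpha on trials with labels[t] == 1 (exploit).
    Returns (nll, n_floored).
    """
    q = np.full(3, 0.5)
    ck = np.zeros(3)
    nll = 0.0
    n_floored = 0
    for t in range(choices.shape[0]):
        x0 = beta * (tau * q[0] + (1.0 - tau) * ck[0])
        x1 = beta * (tau * q[1] + (1.0 - tau) * ck[1])
        x2 = beta * (tau * q[2] + (1.0 - tau) * ck[2])
        m = max(x0, max(x1, x2))
        lse = m + np.log(np.exp(x0 - m) + np.exp(x1 - m) + np.exp(x2 - m))
        c = choices[t]
        if c == 0:
            logp = x0 - lse
        elif c == 1:
            logp = x1 - lse
        else:
            logp = x2 - lse
        if logp < LOG_FLOOR:
            logp = LOG_FLOOR
            n_floored += 1
        nll -= logp
        rate = alpha
        if gamma >= 0.0 and labels[t] == 1:
            rate = gamma * alpha
        q[c] += rate * (rewards[t] - q[c])
        for k in range(3):
            target = 1.0 if k == c else 0.0
            ck[k] += alpha_c * (target - ck[k])
    return nll, n_floored


@njit(cache=True)
def _transition_matrix(a, b):
    P = np.zeros((4, 4))
    P[0, 0] = 1.0 - 3.0 * b
    P[0, 1] = b
    P[0, 2] = b
    P[0, 3] = b
    for k in range(1, 4):
        P[k, 0] = a
        P[k, k] = 1.0 - a
    return P


@njit(cache=True)
def _emission(choice):
    """Emission probabilities of the 4 states for a 0-based choice."""
    e = np.zeros(4)
    e[0] = 1.0 / 3.0
    e[choice + 1] = 1.0
    return e


@njit(cache=True)
def hmm_forward_backward(choices, a, b):
    """Scaled forward-backward for the tied explore/exploit HMM.

    Trial 1 starts in explore with probability 1. Returns
    (loglik, gamma (T,4), n_ee, d_e, n_xe, d_x) where the last four are
    expected tied transition counts: exploit->explore numerator and
    exploit-occupancy denominator, explore->exploit numerator and
    explore-occupancy denominator.
    """
    T = choices.shape[0]
    P = _transition_matrix(a, b)
    alpha = np.zeros((T, 4))
    scale = np.zeros(T)
    e0 = _emission(choices[0])
    alpha[0, 0] = e0[0]  # forced initial explore state
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, T):
        e = _emission(choices[t])
        for j in range(4):
            s = 0.0
            for i in range(4):
                s += alpha[t - 1, i] * P[i, j]
            alpha[t, j] = s * e[j]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]
    loglik = np.log(scale).sum()

    beta_s = np.zeros((T, 4))
    beta_s[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        e = _emission(choices[t + 1])
        for i in range(4):
            s = 0.0
            for j in range(4):
                s += P[i, j] * e[j] * beta_s[t + 1, j]
            beta_s[t, i] = s / scale[t + 1]

    gamma = alpha * beta_s
    # renormalize against scaling round-off
    for t in range(T):
        gamma[t] /= gamma[t].sum()

    n_ee = 0.0  # expected exploit -> explore transitions
    d_e = 0.0  # expected exploit occupancy with a successor trial
    n_xe = 0.0  # expected explore -> exploit transitions
    d_x = 0.0  # expected explore occupancy with a successor trial
    for t in range(T - 1):
        e = _emission(choices[t + 1])
        for i in range(4):
            for j in range(4):
                if P[i, j] == 0.0:
                    continue
                xi = alpha[t, i] * P[i, j] * e[j] * beta_s[t + 1, j] / scale[t + 1]
                if i >= 1 and j == 0:
                    n_ee += xi
                if i == 0 and j >= 1:
                    n_xe += xi
        d_x += gamma[t, 0]
        d_e += gamma[t, 1] + gamma[t, 2] + gamma[t, 3]
    return loglik, gamma, n_ee, d_e, n_xe, d_x


@njit(cache=True)
def hmm_forward_loglik(choices, a, b):
    T = choices.shape[0]
    P = _transition_matrix(a, b)
    prev = np.zeros(4)
    prev[0] = _emission(choices[0])[0]
    c0 = prev.sum()
    prev /= c0
    loglik = np.log(c0)
    cur = np.zeros(4)
    for t in range(1, T):
        e = _emission(choices[t])
        for j in range(4):
            s = 0.0
            for i in range(4):
                s += prev[i] * P[i, j]
            cur[j] = s * e[j]
        c = cur.sum()
        loglik += np.log(c)
        for j in range(4):
            prev[j] = cur[j] / c
    return loglik


@njit(cache=True)
def hmm_em(choices_flat, offsets, a0, b0, tol, max_iter):
    """Baum-Welch with tied parameters over one or more choice sequences.

    ``choices_flat`` concatenates 0-based choice sequences; ``offsets``
    gives the start index of each sequence plus the total length at the
    end. Returns (a, b, loglik, n_iter, converged).
    """
    a, b = a0, b0
    n_seq = offsets.shape[0] - 1
    prev_ll = -np.inf
    n_iter = 0
    converged = False
    for it in range(max_iter):
        n_iter = it + 1
        ll = 0.0
        n_ee = 0.0
        d_e = 0.0
        n_xe = 0.0
        d_x = 0.0
        for s in range(n_seq):
            seq = choices_flat[offsets[s]: offsets[s + 1]]
            sll, _, s_nee, s_de, s_nxe, s_dx = hmm_forward_backward(seq, a, b)
            ll += sll
            n_ee += s_nee
            d_e += s_de
            n_xe += s_nxe
            d_x += s_dx
        if ll - prev_ll < tol and it > 0:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
        if d_e > 0.0:
            a = n_ee / d_e
        if d_x > 0.0:
            b = n_xe / (3.0 * d_x)
        a = min(max(a, 1e-8), 1.0 - 1e-8)
        b = min(max(b, 1e-8), 1.0 / 3.0 - 1e-8)
    return a, b, prev_ll, n_iter, converged
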