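"""Compiled inner loop of the trial-wise likelihood.

The hierarchical EM fit evaluates the session likelihood tens of
thousands of times, so the sequential trial loop is JIT-compiled with
numba. The slow-path equivalents (`twostep.model.stage1_policy` etc.)
define the semantics; the test suite asserts exact agreement.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Floor applied to choice probabilities before taking logs so the
#: objective stays finite under extreme parameters.
PROB_FLOOR = 1e-12


@njit(cache=True)
def session_loglik_core(
    choice1: np.ndarray,
    state2: np.ndarray,
    choice2: np.ndarray,
    reward: np.ndarray,
    theta: np.ndarray,
    p_common: float,
):  # pragma: no cover - exercised via session_log_likelihood
    """Log-likelihood of one session under native-scale parameters.

    theta = (beta_MB, beta_MF, beta_2, alpha_1, alpha_2, lam, p_rep).
    Returns (loglik, per-trial stage-1 predictive probabilities).
    """
    b_mb, b_mf, b_2, a_1, a_2, lam, p_rep = (
        theta[0], theta[1], theta[2], theta[3], theta[4], theta[5], theta[6],
    )
    n = choice1.shape[0]
    q1 = np.zeros(2)
    q2 = np.zeros((2, 2))
    prev = -1
    ll = 0.0
    p1_out = np.empty(n)
    for t in range(n):
        a1 = choice1[t]
        s2 = state2[t]
        a2 = choice2[t]
        r = reward[t]

        # Bellman backup over the known 70/30 transition structure
        qmax0 = q2[0, 0] if q2[0, 0] >= q2[0, 1] else q2[0, 1]
        qmax1 = q2[1, 0] if q2[1, 0] >= q2[1, 1] else q2[1, 1]
        qmb0 = p_common * qmax0 + (1.0 - p_common) * qmax1
        qmb1 = (1.0 - p_common) * qmax0 + p_common * qmax1

        v0 = b_mb * qmb0 + b_mf * q1[0]
        v1 = b_mb * qmb1 + b_mf * q1[1]
        if prev == 0:
            v0 += p_rep
        elif prev == 1:
            v1 += p_rep
        vmax = v0 if v0 >= v1 else v1
        e0 = np.exp(v0 - vmax)
        e1 = np.exp(v1 - vmax)
        p1 = (e0 if a1 == 0 else e1) / (e0 + e1)
        if p1 < PROB_FLOOR:
            p1 = PROB_FLOOR
        p1_out[t] = p1
        ll += np.log(p1)

        w0 = b_2 * q2[s2, 0]
        w1 = b_2 * q2[s2, 1]
        wmax = w0 if w0 >= w1 else w1
        f0 = np.exp(w0 - wmax)
        f1 = np.exp(w1 - wmax)
        p2 = (f0 if a2 == 0 else f1) / (f0 + f1)
        if p2 < PROB_FLOOR:
            p2 = PROB_FLOOR
        ll += np.log(p2)

        # SARSA(lambda): delta1 uses pre-reward-update Q2
        delta1 = q2[s2, a2] - q1[a1]
        delta2 = r - q2[s2, a2]
        q1[a1] = q1[a1] + a_1 * delta1 + a_1 * lam * delta2
        q2[s2, a2] = q2[s2, a2] + a_2 * delta2
        prev = a1
    return ll, p1_out


@njit(cache=True)
def subject_negative_objective_core(
    vec14: np.ndarray,
    choice1: np.ndarray,
    state2: np.ndarray,
    choice2: np.ndarray,
    reward: np.ndarray,
    sess_bounds: np.ndarray,
    sess_codes: np.ndarray,
    prior_mean: np.ndarray,
    prior_var: np.ndarray,
    p_common: float,
) -> float:  # pragma: no cover - exercised via penalized_objective
    """-(sum of session log-likelihoods + log Gaussian prior) for one subject.

    Sessions are stored concatenated; ``sess_bounds`` holds start/stop
    offsets and ``sess_codes`` the +-0.5 effect codes applied to the
    session-difference half of ``vec14``.
    """
    total = 0.0
    theta = np.empty(7)
    for s in range(sess_codes.shape[0]):
        code = sess_codes[s]
        for k in range(7):
            u = vec14[k] + code * vec14[7 + k]
            if k < 3:
                theta[k] = np.exp(u)
            elif k < 6:
                theta[k] = 1.0 / (1.0 + np.exp(-u))
            else:
                theta[k] = u
        lo, hi = sess_bounds[s], sess_bounds[s + 1]
        ll, _ = session_loglik_core(
            choice1[lo:hi], state2[lo:hi], choice2[lo:hi], reward[lo:hi],
            theta, p_common,
        )
        total += ll
    logprior = 0.0
    for k in range(14):
        z = vec14[k] - prior_mean[k]
        logprior -= 0.5 * (np.log(2.0 * np.pi * prior_var[k]) + z * z / prior_var[k])
    return -(total + logprior)
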