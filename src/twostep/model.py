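"""Dual-control computational model of two-step choice.

Two valuation systems jointly drive the first-stage choice: a model-free
SARSA(lambda) learner maintaining first-stage action values Q1_MF, and a
model-based planner that evaluates first-stage actions by a Bellman
backup of second-stage values over the known 70/30 transition structure.
Both systems share the second-stage values Q2, which are learned by
simple delta-rule updates. Choices are softmax in a net preference

    beta_MF * Q1_MF(a) + beta_MB * Q_MB(a) + p_rep * rep(a)

at stage 1 (rep(a) = 1 for the previous trial's choice) and
``beta_2 * Q2(s2, a)`` at stage 2. Seven free parameters: the two system
weights, the second-stage inverse temperature, two learning rates, the
eligibility parameter lambda (how strongly second-stage reward prediction
errors update first-stage model-free values), and a perseveration weight.

For estimation the bounded parameters are mapped to an unbounded scale:
log for the betas and logit for the learning rates and lambda; the
perseveration weight is unbounded already.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._likelihood import PROB_FLOOR, session_loglik_core
from .task import (
    TRIAL_COLUMNS,
    RewardWalk,
    TaskConfig,
    TrialRecord,
    common_destination,
    generate_reward_walk,
    sample_reward,
    sample_transition,
)

__all__ = [
    "AgentParameters",
    "ValueState",
    "UpdateTrace",
    "PARAM_NAMES",
    "to_unbounded",
    "to_native",
    "model_based_values",
    "stage1_policy",
    "stage2_policy",
    "update_values",
    "session_log_likelihood",
    "simulate_agent",
    "trials_to_arrays",
]

#: Canonical parameter order on both scales (CSV column names use these).
PARAM_NAMES = ["beta_MB", "beta_MF", "beta_2", "alpha_1", "alpha_2", "lambda", "rep"]


@dataclass(frozen=True)
class AgentParameters:
    """The seven native-scale model parameters."""

    beta_MB: float
    beta_MF: float
    beta_2: float
    alpha_1: float
    alpha_2: float
    lam: float
    p_rep: float

    def __post_init__(self) -> None:
        if min(self.beta_MB, self.beta_MF, self.beta_2) < 0:
            raise ValueError("inverse-temperature weights must be non-negative")
        for name in ("alpha_1", "alpha_2", "lam"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.beta_MB, self.beta_MF, self.beta_2,
             self.alpha_1, self.alpha_2, self.lam, self.p_rep]
        )


@dataclass
class ValueState:
    """Learned values carried across trials within a session."""

    Q1_MF: np.ndarray = field(default_factory=lambda: np.zeros(2))
    Q2: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    prev_choice1: Optional[int] = None


@dataclass(frozen=True)
class UpdateTrace:
    """Prediction errors produced by one trial's value update."""

    delta1: float
    delta2: float


def to_unbounded(params: AgentParameters) -> np.ndarray:
    """Map native parameters to the unconstrained estimation scale.

    Order: (log beta_MB, log beta_MF, log beta_2, logit alpha_1,
    logit alpha_2, logit lambda, p_rep).
    """
    if min(params.beta_MB, params.beta_MF, params.beta_2) <= 0:
        raise ValueError("log transform requires strictly positive beta weights")
    for name in ("alpha_1", "alpha_2", "lam"):
        v = getattr(params, name)
        if v <= 0.0 or v >= 1.0:
            raise ValueError(f"logit transform requires {name} strictly inside (0, 1)")
    return np.array(
        [
            np.log(params.beta_MB),
            np.log(params.beta_MF),
            np.log(params.beta_2),
            logit(params.alpha_1),
            logit(params.alpha_2),
            logit(params.lam),
            params.p_rep,
        ]
    )


def to_native(vec: Sequence[float]) -> AgentParameters:
    """Inverse of :func:`to_unbounded`; always yields valid parameters."""
    v = np.asarray(vec, dtype=float)
    if v.shape != (7,):
        raise ValueError(f"expected a 7-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("unbounded parameter vector must be finite")
    return AgentParameters(
        beta_MB=float(np.exp(v[0])),
        beta_MF=float(np.exp(v[1])),
        beta_2=float(np.exp(v[2])),
        alpha_1=float(expit(v[3])),
        alpha_2=float(expit(v[4])),
        lam=float(expit(v[5])),
        p_rep=float(v[6]),
    )


def model_based_values(Q2: np.ndarray, config: TaskConfig) -> np.ndarray:
    """Bellman backup: expected best second-stage value of each stage-1 action."""
    qmax = np.max(np.asarray(Q2, dtype=float), axis=1)
    pc, pr = config.p_common, config.p_rare
    return np.array(
        [pc * qmax[0] + pr * qmax[1], pr * qmax[0] + pc * qmax[1]]
    )


def _softmax2(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - np.max(v))
    return e / e.sum()


def stage1_policy(
    state: ValueState, params: AgentParameters, config: TaskConfig
) -> np.ndarray:
    """Softmax stage-1 choice probabilities from the mixed MB/MF preference."""
    q_mb = model_based_values(state.Q2, config)
    net = params.beta_MF * state.Q1_MF + params.beta_MB * q_mb
    if state.prev_choice1 is not None:
        rep = np.zeros(2)
        rep[state.prev_choice1] = 1.0
        net = net + params.p_rep * rep
    return _softmax2(net)


def stage2_policy(state: ValueState, state2: int, params: AgentParameters) -> np.ndarray:
    """Softmax second-stage choice probabilities in the visited state."""
    return _softmax2(params.beta_2 * state.Q2[state2])


def update_values(
    state: ValueState, trial: TrialRecord, params: AgentParameters
) -> tuple[ValueState, UpdateTrace]:
    """Apply one trial's SARSA(lambda) / delta-rule value update.

    With pre-update values: delta1 = Q2(s2,a2) - Q1_MF(a1) and
    delta2 = r - Q2(s2,a2); the first-stage value moves by
    alpha_1*delta1 + alpha_1*lambda*delta2 (the eligibility-weighted
    stage-skipping update) and the visited second-stage value by
    alpha_2*delta2.
    """
    a1, s2, a2, r = trial.choice1, trial.state2, trial.choice2, trial.reward
    delta1 = float(state.Q2[s2, a2] - state.Q1_MF[a1])
    delta2 = float(r - state.Q2[s2, a2])
    q1 = state.Q1_MF.copy()
    q2 = state.Q2.copy()
    q1[a1] += params.alpha_1 * delta1 + params.alpha_1 * params.lam * delta2
    q2[s2, a2] += params.alpha_2 * delta2
    return ValueState(Q1_MF=q1, Q2=q2, prev_choice1=a1), UpdateTrace(delta1, delta2)


def trials_to_arrays(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Coerce a trial table (DataFrame or TrialRecord sequence) to int arrays."""
    if isinstance(trials, pd.DataFrame):
        idx = trials["trial"].to_numpy()
        cols = (
            trials["choice1"].to_numpy(np.int64),
            trials["state2"].to_numpy(np.int64),
            trials["choice2"].to_numpy(np.int64),
            trials["reward"].to_numpy(np.int64),
        )
    else:
        records = list(trials)
        idx = np.array([t.trial_index for t in records])
        cols = tuple(
            np.array([getattr(t, f) for t in records], dtype=np.int64)
            for f in ("choice1", "state2", "choice2", "reward")
        )
    if len(idx) == 0:
        raise ValueError("empty trial sequence")
    if not np.array_equal(idx, np.arange(idx[0], idx[0] + len(idx))):
        raise ValueError("trials must be sorted and contiguous in trial index")
    return cols


def session_log_likelihood(
    params: AgentParameters, trials, config: TaskConfig
) -> tuple[float, np.ndarray]:
    """Trial-wise log-likelihood of one session of observed choices.

    Values start at zero, policies and updates interleave exactly as in
    :func:`simulate_agent`, and per-trial probabilities are floored at
    1e-12 before the log. Returns the summed log-likelihood and the
    per-trial stage-1 predictive probabilities of the observed choices.
    """
    c1, s2, c2, r = trials_to_arrays(trials)
    ll, p1 = session_loglik_core(c1, s2, c2, r, params.as_array(), config.p_common)
    return float(ll), p1


def simulate_agent(
    params: AgentParameters,
    config: TaskConfig,
    seed: int | np.random.Generator,
    subject_id: str = "s0",
    session: Optional[int] = None,
    walk: Optional[RewardWalk] = None,
) -> tuple[pd.DataFrame, list[RewardWalk]]:
    """Simulate an agent playing the task with the generative model.

    By default generates ``config.n_sessions`` sessions of
    ``config.n_trials_per_session`` trials each, with a fresh reward walk
    and zero-initialised values per session. Passing ``session`` (and
    optionally a fixed ``walk``) simulates that single session instead.
    Returns the trial table plus the latent walks, one per session.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sessions = [session] if session is not None else list(range(1, config.n_sessions + 1))
    rows: list[tuple] = []
    walks: list[RewardWalk] = []
    for sess in sessions:
        w = walk if walk is not None else generate_reward_walk(
            config, config.n_trials_per_session, rng
        )
        walks.append(w)
        state = ValueState()
        for t in range(w.n_trials):
            p1 = stage1_policy(state, params, config)
            a1 = int(rng.random() < p1[1])
            s2, label = sample_transition(config, a1, rng)
            p2 = stage2_policy(state, s2, params)
            a2 = int(rng.random() < p2[1])
            r = sample_reward(w.probs[t], s2, a2, rng)
            rows.append((subject_id, sess, t + 1, a1, label, s2, a2, r))
            trial = TrialRecord(
                choice1=a1, transition=label, state2=s2, choice2=a2, reward=r,
                subject_id=subject_id, session=sess, trial_index=t + 1,
            )
            state, _ = update_values(state, trial, params)
    frame = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return frame, walks
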