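"""Generative model of the two-step Markov decision task environment.

The task has two stages. A first-stage choice between two actions leads
probabilistically (common transition 70%, rare 30%) to one of two
second-stage states, each offering two actions. Each of the four terminal
actions pays a unit reward with a probability that drifts across trials as
an independent Gaussian random walk reflected at fixed bounds, so the best
option keeps changing and subjects must keep learning.

Coordinate conventions: actions and states are coded 0/1, the common
mapping is action 0 -> state 0 and action 1 -> state 1, and trial indices
are 1-based within a session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TaskConfig",
    "RewardWalk",
    "TrialRecord",
    "TRIAL_COLUMNS",
    "common_destination",
    "generate_reward_walk",
    "sample_transition",
    "sample_reward",
]

#: Column order of the canonical trial table (CSV schema).
TRIAL_COLUMNS = [
    "subject_id",
    "session",
    "trial",
    "choice1",
    "transition",
    "state2",
    "choice2",
    "reward",
]


@dataclass(frozen=True)
class TaskConfig:
    """Fixed structure of the two-step task.

    Parameters
    ----------
    p_common:
        Probability that a first-stage action leads to its common
        destination state. The rare probability is ``1 - p_common``.
    walk_sd:
        Per-trial standard deviation of the Gaussian innovations of the
        reward-probability random walks (probability units).
    walk_lo, walk_hi:
        Reflecting bounds of the reward-probability walks.
    n_trials_per_session, n_sessions:
        Session layout (201 trials, two sessions by default). The 201
        trials run in three blocks of 67 separated by breaks; the blocks
        have no computational effect and are not modelled.
    reward_magnitude:
        Cosmetic label for the unit reward (currency framing only).
    """

    p_common: float = 0.7
    walk_sd: float = 0.025
    walk_lo: float = 0.25
    walk_hi: float = 0.75
    n_trials_per_session: int = 201
    n_sessions: int = 2
    reward_magnitude: str = "20 cents"

    def __post_init__(self) -> None:
        if not 0.5 < self.p_common < 1.0:
            raise ValueError(f"p_common must lie in (0.5, 1), got {self.p_common}")
        if not 0.0 <= self.walk_lo < self.walk_hi <= 1.0:
            raise ValueError(
                f"need 0 <= walk_lo < walk_hi <= 1, got [{self.walk_lo}, {self.walk_hi}]"
            )
        if self.walk_sd < 0:
            raise ValueError("walk_sd must be non-negative")
        if self.n_trials_per_session < 1 or self.n_sessions < 1:
            raise ValueError("session layout counts must be positive")

    @property
    def p_rare(self) -> float:
        return 1.0 - self.p_common


@dataclass(frozen=True)
class RewardWalk:
    """Latent reward probabilities, one row per trial.

    ``probs`` has shape (n_trials, 4); column ``2*state2 + choice2`` holds
    the reward probability of that terminal action.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError(f"walk must be (n_trials, 4), got {p.shape}")
        object.__setattr__(self, "probs", p)

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]

    def prob(self, trial_index: int, state2: int, choice2: int) -> float:
        """Reward probability of terminal action (state2, choice2) on a 0-based trial."""
        return float(self.probs[trial_index, 2 * state2 + choice2])


@dataclass(frozen=True)
class TrialRecord:
    """One two-step trial; the unit of likelihood evaluation."""

    choice1: int
    transition: str
    state2: int
    choice2: int
    reward: int
    subject_id: str = "s0"
    session: int = 1
    trial_index: int = 1

    def __post_init__(self) -> None:
        if self.choice1 not in (0, 1) or self.choice2 not in (0, 1):
            raise ValueError("choices must be coded 0/1")
        if self.state2 not in (0, 1):
            raise ValueError("state2 must be coded 0/1")
        if self.reward not in (0, 1):
            raise ValueError("reward must be 0 or 1")
        expected = "common" if self.state2 == common_destination(self.choice1) else "rare"
        if self.transition != expected:
            raise ValueError(
                f"transition label {self.transition!r} inconsistent with "
                f"choice1={self.choice1}, state2={self.state2} (expected {expected!r})"
            )


def common_destination(choice1: int) -> int:
    """The second-stage state commonly reached from a first-stage action."""
    if choice1 not in (0, 1):
        raise ValueError(f"choice1 must be 0 or 1, got {choice1}")
    return choice1


def _reflect(x: float, lo: float, hi: float) -> float:
    # Mirror overshoot back into [lo, hi]; repeat for pathological jumps.
    while x < lo or x > hi:
        if x < lo:
            x = 2.0 * lo - x
        else:
            x = 2.0 * hi - x
    return x


def generate_reward_walk(
    config: TaskConfig,
    n_trials: int,
    seed: int | np.random.Generator,
    initial: Optional[Sequence[float]] = None,
) -> RewardWalk:
    """Simulate the four reflected Gaussian reward-probability walks.

    ``initial`` fixes the starting row; by default the four starting
    probabilities are drawn uniformly within the reflecting bounds from
    the same seeded stream. Deterministic given the seed.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = np.empty((n_trials, 4), dtype=float)
    if initial is None:
        probs[0] = rng.uniform(config.walk_lo, config.walk_hi, size=4)
    else:
        start = np.asarray(initial, dtype=float)
        if start.shape != (4,):
            raise ValueError("initial must be a length-4 probability vector")
        if np.any(start < config.walk_lo) or np.any(start > config.walk_hi):
            raise ValueError("initial walk values must lie within the reflecting bounds")
        probs[0] = start
    for t in range(1, n_trials):
        step = probs[t - 1] + rng.normal(0.0, config.walk_sd, size=4)
        probs[t] = [_reflect(v, config.walk_lo, config.walk_hi) for v in step]
    return RewardWalk(probs)


def sample_transition(
    config: TaskConfig, choice1: int, rng: np.random.Generator
) -> tuple[int, str]:
    """Draw the second-stage state for a first-stage action.

    Returns ``(state2, label)`` where the action's common destination is
    reached with probability ``p_common`` and the label matches the draw.
    """
    common = common_destination(choice1)
    if rng.random() < config.p_common:
        return common, "common"
    return 1 - common, "rare"


def sample_reward(
    walk_row: Sequence[float], state2: int, choice2: int, rng: np.random.Generator
) -> int:
    """Bernoulli reward for terminal action (state2, choice2) under one walk row."""
    row = np.asarray(walk_row, dtype=float)
    if row.shape != (4,):
        raise ValueError("walk_row must have exactly 4 entries")
    p = row[2 * state2 + choice2]
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"reward probability out of [0, 1]: {p}")
    return int(rng.random() < p)
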