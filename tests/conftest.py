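import numpy as np
import pytest

import twostep as ts


@pytest.fixture(scope="session")
def task() -> ts.TaskConfig:
    return ts.TaskConfig()


@pytest.fixture(scope="session")
def mixed_agent() -> ts.AgentParameters:
    """A moderate hybrid agent with all systems engaged."""
    return ts.AgentParameters(
        beta_MB=1.4, beta_MF=0.7, beta_2=2.0,
        alpha_1=0.35, alpha_2=0.6, lam=0.5, p_rep=0.3,
    )


@pytest.fixture(scope="session")
def small_session(task, mixed_agent):
    """One simulated 201-trial session of the mixed agent."""
    frame, walks = ts.simulate_agent(mixed_agent, task, seed=7, session=1)
    return frame, walks[0]


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 6-subject, 60-trial-per-session cohort for fast EM tests."""
    spec = ts.CohortSpec(n_subjects=6)
    cfg = ts.TaskConfig(n_trials_per_session=60)
    return ts.generate_cohort(spec, seed=42, task=cfg), cfg


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
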