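"""Fit the seven-parameter dual-control model to one simulated subject.

Simulates a subject with known parameters, computes the session
log-likelihood surface's MAP under a weak population prior, and compares
the estimate with the truth. With only 2 x 201 trials the posterior is
wide for some parameters - exactly why the full pipeline fits all
subjects jointly under a hierarchical prior.
"""

import numpy as np
import pandas as pd

import twostep as ts
from twostep.fitting import (
    GroupPrior, SubjectData, SubjectParameterVector,
    fit_subject_map, predictive_accuracy, subject_parameters_for_session,
)

task = ts.TaskConfig()
truth = SubjectParameterVector(
    mu=np.array([0.8, 0.0, 1.1, -0.3, 0.4, -0.3, 1.2]),  # unbounded scale
    delta=np.zeros(7),
)

rng = np.random.default_rng(7)
frames = []
for session in (1, 2):
    params = subject_parameters_for_session(truth, session)
    frame, _ = ts.simulate_agent(params, task, rng, subject_id="s0", session=session)
    frames.append(frame)
data = SubjectData.from_frame(pd.concat(frames))

prior = GroupPrior(np.zeros(14), np.full(14, 4.0))
fit = fit_subject_map(data, prior, task)

print(f"{'parameter':>10s} {'true':>8s} {'MAP':>8s} {'post SD':>8s}")
for k, name in enumerate(ts.PARAM_NAMES):
    sd = np.sqrt(fit.posterior_var[k])
    print(f"{name:>10s} {truth.mu[k]:8.3f} {fit.map_estimate.mu[k]:8.3f} {sd:8.3f}")

acc = predictive_accuracy(fit, data, task)
print(f"\nmean stage-1 predictive probability at the MAP: {acc:.3f}")
print("(0.5 would be chance; the study this emulates reported ~0.69)")
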