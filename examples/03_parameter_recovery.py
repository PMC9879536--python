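"""Small parameter-recovery check of the hierarchical EM.

Simulates a compact cohort from known parameters, refits it, and prints
the per-parameter correlation between truth and recovery. At desk scale
(8 subjects, 120 trials per session) correlations are rougher than at
the study's full size; the acceptance script runs the full 32-subject,
201-trial version.
"""

import numpy as np

import twostep as ts
from twostep.fitting import EMOptions, SubjectParameterVector, parameter_recovery

task = ts.TaskConfig(n_trials_per_session=120)
rng = np.random.default_rng(3)
truths = [
    SubjectParameterVector(
        mu=np.array([0.8, 0.0, 1.1, -0.3, 0.4, -0.3, 1.2]) + rng.normal(0, 0.5, 7),
        delta=rng.normal(0, 0.1, 7),
    )
    for _ in range(8)
]

report = parameter_recovery(truths, task, seed=4, options=EMOptions(max_iter=8))
print("true-vs-recovered Pearson r (unbounded subject means):")
for name, r in report.correlations.items():
    print(f"  {name:10s} {r: .3f}")
print("\nThe model-based weight is the scientifically critical parameter;")
print("at full study scale its recovery correlation is typically ~0.8.")
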