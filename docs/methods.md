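# Methods

## Task environment

The simulated two-step task follows the standard design: two first-stage
actions, two second-stage states with two actions each, fixed transition
structure (each first-stage action reaches its *common* state with
probability 0.7, the other with 0.3; the common mapping is action 0 →
state 0, action 1 → state 1), and binary rewards whose probabilities
follow four independent Gaussian random walks reflected at 0.25 and
0.75. The per-trial innovation SD defaults to 0.025 — the value used in
the task this design descends from; it is config-exposed because the
study itself does not state it, as are the walk starting values (drawn
uniformly within the bounds by default). Sessions are 201 trials; the
session's three 67-trial blocks are breaks only and have no
computational effect. Reflection mirrors any overshoot
(`p → 2·bound − p`, applied repeatedly), which preserves the bounds for
arbitrary innovations.

## Choice model

Seven parameters: model-based weight β_MB ≥ 0, model-free weight
β_MF ≥ 0, second-stage inverse temperature β₂ ≥ 0, learning rates
α₁, α₂ ∈ [0,1], eligibility λ ∈ [0,1], perseveration p (unbounded).
Value updates and policies are given in the README. Numerical choices:

- All Q values start at 0 at the beginning of *each* session; nothing is
  carried across sessions. The sessions are separated by breaks with
  interventions, and the session-difference parameters absorb residual
  differences; resets keep the sessions exchangeable.
- δ₁ uses the pre-reward-update Q2 (standard SARSA ordering).
- Both systems share the same Q2; the model-based system evaluates
  stage 1 by a Bellman backup over that shared table.
- The perseveration indicator refers only to the immediately preceding
  trial within the same session (zero on each session's first trial),
  and enters stage 1 only.
- Softmaxes subtract the max before exponentiating; choice probabilities
  are floored at 1e−12 before logs so the objective stays finite under
  extreme parameters.
- With rewards in {0,1} and valid rates, every Q stays in [0,1]: the Q1
  update is the convex combination (1−α₁)Q1 + α₁(1−λ)Q2 + α₁λr.

The likelihood's inner loop is compiled with numba for estimation speed;
the pure-Python policy/update functions define the semantics and the
test suite asserts exact (1e−10) agreement between the two paths and an
independent straight-line recomputation.

## Hierarchical estimation

Bounded parameters are mapped to an unbounded scale (log β, logit α/λ).
Each subject is a 14-vector: 7 cross-session means μ plus 7 session
differences δ, with session-s parameters μ + c_s·δ under effect codes
c₁ = −0.5, c₂ = +0.5. Subjects share a diagonal Gaussian population
prior (diagonal keeps the M-step closed-form and matches common practice
for this EM scheme). The E-step finds each subject's MAP by multi-start
L-BFGS-B (zero vector, prior mean, a seeded perturbation of the prior
mean; from the second EM iteration the previous MAP warm-starts the
optimizer) and Laplace-approximates the posterior by the diagonal of the
inverse of a full central-difference Hessian (step 1e−3) at the MAP.
Using the full-Hessian inverse matters: inverting only the Hessian
diagonal underestimates marginal variances when parameters are
correlated, which biases the M-step's variance update downward and
over-shrinks subjects. The M-step is the moment update
mean = avg(MAP), var = avg(MAP² + Laplace var) − mean², with variances
floored at 1e−4. Iteration stops when the prior mean moves < 1e−3
(max 30 iterations; the run returns the best iterate with a warning
otherwise). Convergence is monitored on the Laplace approximation of the
negative log marginal evidence, which this scheme drives downward; the
EM-health test asserts monotone non-increase at tolerance 1e−2/step.
Laplace variances are floored at 1e−6; a non-positive-definite numerical
Hessian falls back to univariate curvatures or, failing that, the prior
variance. Downstream association analyses use only the μ components on
the unbounded scale (the estimation space); the session differences are
estimated but discarded, since session effects are not the target of the
trait analyses.

## Synthetic cohort

The generator emulates the study design: 32 subjects × 2 sessions × 201
trials, trait scores (MW-S 4.11 ± 1.11, MW-D 4.49 ± 1.06 on a 1–7 scale,
clipped; DSST standardized, as no moments are published for this
sample). Unbounded parameters are drawn per subject as
group mean + slope·z(trait) + Gaussian residual; only the log
model-based weight carries nonzero slopes: −0.30 per z-unit of MW-S (the
published coefficient) and +0.235 per z-unit of DSST, the value at which
the standardized DSST coefficient is ≈ 0.374 given the residual SD
(solve s/√(0.25 + 0.09 + s²) = 0.374). MW-D is generated with no planted
effect. Session differences are N(0, 0.1²).

The generative group moments are calibrated to the study's printed
behavioural statistics and then frozen:
`group_mean = (log 2.2, log 1.0, log 3.0, −0.3, 0.36, −0.3, 1.2)`,
`group_sd = (0.5, 0.5, 0.5, 1.0, 0.83, 1.0, 0.5)` in the order
(log β_MB, log β_MF, log β₂, logit α₁, logit α₂, logit λ, p). The α₂
moments reproduce the reported native-scale 0.59 ± 0.20 via the delta
method (logit 0.59 ≈ 0.36, SD 0.20/(0.59·0.41) ≈ 0.83); the β and
perseveration moments reproduce the reported mean stage-1 predictive
probability of ≈ 0.69 and near-chance first-stage accuracy. One residual
mismatch is documented below under limitations.

What the generator does *not* emulate: response times, item-level
questionnaires, attentional lapses or other off-task dynamics, and any
non-stationarity in the human data beyond what the 7-parameter model
expresses. Passing tests therefore show that the pipeline is correct and
well-calibrated *for data generated by the model it fits*; they cannot
show that the model describes human behaviour.

## Statistics

Linear effects are OLS of the per-subject unbounded estimate on the
trait (complete cases; one-tailed p in the prespecified direction).
Median splits assign subjects at the median to the low group and reduce
to a pooled-variance t-test. The within-subject contrasts (system ×
trait; MW-S vs DSST association comparison) are random-intercept mixed
models with effect-coded (±0.5) factors; p-values use a t reference with
residual degrees of freedom (the simplest defensible choice; a singular
fit falls back to subject-demeaned OLS with a note in the result). The
stay-probability analysis computes per-subject 2×2 cell proportions and
per-subject logistic regressions of stay on effect-coded previous
reward, previous transition, and their product, then tests the
coefficients across subjects; subject-sessions with fewer than two
trials are excluded with a warning, and non-converged (separated)
subject fits are flagged and dropped from the group tests. No
multiple-comparison correction is applied, matching the analysis this
mirrors.

Bayes factors use a normal-likelihood Savage–Dickey ratio: the
coefficient estimate enters as N(b̂, SE²), conjugate with the (optionally
sign-truncated, renormalized) Gaussian prior, and BF₁₀ = prior
density/posterior density at 0. The informed prior for the
mind-wandering effects on the decision weights is N(−0.24, 0.11²) (a
previously estimated processing-speed effect); other parameters use
N(0.32, 0.28²). The sensitivity curve varies the prior SD with the prior
truncated to the hypothesized sign; because the original tool's exact
likelihood is unknown, only qualitative Bayes-factor categories (e.g.,
BF > 3) are asserted, never exact published values. The implementation
is verified against brute-force numerical quadrature of the marginal
likelihood ratio (|Δ log BF| < 1e−6) and is invariant to common
rescaling of (b̂, SE, prior mean, prior SD).

## Parameter recovery

Recovery follows the study's procedure: fit the hierarchical EM to a
cohort, treat the per-subject *estimates* as true parameters, simulate
fresh data from them, refit, and correlate truth with recovery per
parameter on the unbounded scale (unbounded axes avoid boundary
compression). Using estimates as truths matters: unconstrained
generative draws occasionally produce subjects with a model-based weight
too small to identify in 402 trials, whose estimates shrink to the group
mean and depress the correlation; estimates-as-truths confines truths to
the identifiable range, which is exactly what the original recovery
measured. At the full design size the model-based weight recovery
correlation is seed-dependent — roughly 0.64–0.88 across cohort
realizations with a median near 0.80 — because with 402 trials the
weight's per-subject measurement noise is comparable to the generator's
between-subject spread; low-information cohort draws depress r. Subjects
with zero between-subject variance are reported as degenerate rather
than silently yielding NaN.

## Problem sizes and runtime choices

The acceptance script runs full-size cohorts (32 × 2 × 201) with the EM
iteration cap at 12 and reports the recovery correlation as a median
over 3 replicates (each replicate is a cohort EM fit plus a second EM on
re-simulated data); this completes in a few minutes on one CPU. The
test suite runs the recovery check as a median over 5 cohort replicates
(the n = 32 sample correlation is noisy), the planted-effect check over
5 replicates at full cohort size with the EM cap at 8, and the
null-calibration check over 30 replicates at a reduced scale
(12 subjects, 100 trials/session, cap 5), with the 10% false-positive
bound assessed at the binomial 99% quantile.

## Known limitations

- Simulated dual-control agents whose determinism matches the reported
  predictive probability (≈ 0.69) track the drifting reward walks
  slightly better than the human group did: their first-stage accuracy
  is ≈ 54–55% against the reported 50.2% (SD 3.1). No setting of the
  7-parameter model reproduces the reported predictive probability,
  second-stage learning rate, and chance-level accuracy simultaneously —
  human choice consistency evidently contained structure (e.g., value-
  independent stickiness or lapses) that this model family cannot
  express. The accuracy check is reported as computed.
- Regressions of MAP estimates on traits are attenuated by hierarchical
  shrinkage (here by roughly 0.6–0.8 depending on the realization), so
  the planted −0.30 slope is recovered with its t-statistic roughly
  preserved but its magnitude biased toward zero; detection power per
  replicate is ≈ 65–75%, in line with the design's published power.
- The population prior is diagonal; parameter correlations are captured
  in each subject's Laplace posterior but not in the group model.
- Mixed-model inference uses residual-df t references, not
  Satterthwaite/Kenward–Roger corrections.
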