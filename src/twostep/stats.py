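"""Trait-association statistics for fitted dual-control parameters.

Covers the behavioural stay-probability markers (reward main effect =
model-free signature, reward x transition interaction = model-based
signature), continuous and median-split linear trait associations,
repeated-measures interaction models (random intercept per subject), and
informed-prior Savage-Dickey Bayes factors with prior-sensitivity
curves. All analyses operate on unbounded-scale subject means, matching
the estimation space. No multiple-comparison correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "EffectResult",
    "BFPrior",
    "StayTable",
    "stay_probability_analysis",
    "linear_effect",
    "median_split_effect",
    "savage_dickey_bf",
    "bf_sensitivity_curve",
    "trait_by_system_interaction",
    "association_comparison",
]


@dataclass(frozen=True)
class EffectResult:
    """A fitted association: coefficient, uncertainty, and tests.

    ``p_one`` is one-tailed in the prespecified ``direction`` (+1/-1):
    half of ``p_two`` when the estimate's sign matches the hypothesis,
    ``1 - p_two/2`` otherwise.
    """

    b: float
    se: float
    t: float
    df: float
    p_two: float
    p_one: float
    bf10: Optional[float] = None
    notes: str = ""


@dataclass(frozen=True)
class BFPrior:
    """Gaussian prior on a regression coefficient for Savage-Dickey tests.

    ``truncated`` restricts the prior to the hypothesized sign;
    ``truncation_sign`` fixes that sign explicitly (defaults to the sign
    of the prior mean).
    """

    mean: float
    sd: float
    truncated: bool = False
    truncation_sign: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("prior sd must be positive")
        if self.truncated and self.truncation_sign is None and self.mean == 0:
            raise ValueError("truncated prior with zero mean needs an explicit sign")

    @property
    def sign(self) -> int:
        if self.truncation_sign is not None:
            return 1 if self.truncation_sign > 0 else -1
        return 1 if self.mean > 0 else -1


def _t_pvalues(t: float, df: float, direction: int) -> tuple[float, float]:
    p_two = float(2.0 * sps.t.sf(abs(t), df))
    if np.sign(t) == np.sign(direction) and t != 0:
        p_one = p_two / 2.0
    else:
        p_one = 1.0 - p_two / 2.0
    return p_two, p_one


def _complete_cases(*arrays: Sequence[float]) -> list[np.ndarray]:
    arrs = [np.asarray(a, dtype=float) for a in arrays]
    n = {a.size for a in arrs}
    if len(n) != 1:
        raise ValueError("inputs must have equal length")
    mask = np.ones(arrs[0].size, dtype=bool)
    for a in arrs:
        mask &= np.isfinite(a)
    return [a[mask] for a in arrs]


def linear_effect(
    estimates: Sequence[float],
    trait: Sequence[float],
    direction: int = -1,
    bf_prior: Optional[BFPrior] = None,
) -> EffectResult:
    """OLS of the per-subject estimate on the trait (with intercept).

    Subjects with missing values are dropped (complete cases). The
    one-tailed p follows ``direction``; if a prior is supplied a
    Savage-Dickey Bayes factor for the slope is attached.
    """
    y, x = _complete_cases(estimates, trait)
    if y.size < 3:
        raise ValueError("need at least 3 complete cases")
    if np.std(x) == 0:
        raise ValueError("trait has zero variance; association undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    b, se, t = float(fit.params[1]), float(fit.bse[1]), float(fit.tvalues[1])
    df = float(fit.df_resid)
    p_two, p_one = _t_pvalues(t, df, direction)
    bf10 = savage_dickey_bf(b, se, bf_prior) if bf_prior is not None else None
    return EffectResult(b=b, se=se, t=t, df=df, p_two=p_two, p_one=p_one, bf10=bf10)


def median_split_effect(
    estimates: Sequence[float],
    trait: Sequence[float],
    direction: int = -1,
    bf_prior: Optional[BFPrior] = None,
) -> EffectResult:
    """High-vs-low trait comparison after a median split.

    Subjects exactly at the median go to the low group; the contrast is
    an OLS on a 0/1 group indicator, equivalent to a pooled-variance
    two-sample t-test (b = high mean - low mean).
    """
    y, x = _complete_cases(estimates, trait)
    if np.std(x) == 0:
        raise ValueError("all trait values tied at the median; split degenerate")
    high = x > np.median(x)
    if high.sum() < 1 or (~high).sum() < 1:
        raise ValueError("median split produced an empty group")
    fit = sm.OLS(y, sm.add_constant(high.astype(float))).fit()
    b, se = float(fit.params[1]), float(fit.bse[1])
    notes = ""
    if se < 1e-10:
        se = 1e-10
        notes = "zero within-group variance; se floored"
    t = b / se
    df = float(fit.df_resid)
    p_two, p_one = _t_pvalues(t, df, direction)
    bf10 = savage_dickey_bf(b, se, bf_prior) if bf_prior is not None else None
    return EffectResult(b=b, se=se, t=t, df=df, p_two=p_two, p_one=p_one,
                        bf10=bf10, notes=notes)


def savage_dickey_bf(b_hat: float, se: float, prior: BFPrior) -> float:
    """Savage-Dickey Bayes factor BF10 for a point null at zero.

    The data enter through a Gaussian likelihood N(b_hat, se^2) for the
    coefficient; combined with the (optionally sign-truncated) Gaussian
    prior this gives a conjugate (truncated) Gaussian posterior, and
    BF10 = prior density at 0 / posterior density at 0, both densities
    renormalized over the truncation region. BF10 > 1 favours an effect.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    post_var = 1.0 / (1.0 / prior.sd**2 + 1.0 / se**2)
    post_mean = post_var * (prior.mean / prior.sd**2 + b_hat / se**2)
    prior_at0 = sps.norm.pdf(0.0, prior.mean, prior.sd)
    post_at0 = sps.norm.pdf(0.0, post_mean, np.sqrt(post_var))
    if prior.truncated:
        # renormalize both densities over the allowed half-line; at the
        # boundary zero the density is the limit from inside the support
        if prior.sign > 0:
            z_prior = sps.norm.sf(0.0, prior.mean, prior.sd)
            z_post = sps.norm.sf(0.0, post_mean, np.sqrt(post_var))
        else:
            z_prior = sps.norm.cdf(0.0, prior.mean, prior.sd)
            z_post = sps.norm.cdf(0.0, post_mean, np.sqrt(post_var))
        prior_at0 /= z_prior
        post_at0 /= z_post
    return float(prior_at0 / post_at0)


def bf_sensitivity_curve(
    b_hat: float,
    se: float,
    prior_mean: float,
    prior_sds: Sequence[float],
    truncated: bool = True,
    truncation_sign: Optional[int] = None,
) -> pd.DataFrame:
    """BF10 as a function of the prior SD (one Savage-Dickey call per point)."""
    sds = np.asarray(prior_sds, dtype=float)
    if sds.size == 0 or np.any(sds <= 0):
        raise ValueError("prior_sds must be a non-empty positive grid")
    rows = [
        {
            "prior_sd": float(s),
            "bf10": savage_dickey_bf(
                b_hat, se,
                BFPrior(prior_mean, float(s), truncated=truncated,
                        truncation_sign=truncation_sign),
            ),
        }
        for s in sds
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stay-probability analysis
# ---------------------------------------------------------------------------

@dataclass
class StayTable:
    """Stay-probability summary of a trial table.

    ``cell_props``: per-subject stay proportions in the 2x2 of previous
    reward x previous transition. ``coefficients``: per-subject logistic
    coefficients of stay on effect-coded (+-0.5) reward, transition, and
    their product. ``group_tests``: one-sample t-tests of the per-subject
    coefficients against zero.
    """

    cell_props: pd.DataFrame
    group_means: pd.Series
    group_sems: pd.Series
    coefficients: pd.DataFrame
    group_tests: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    @property
    def reward_effect_t(self) -> float:
        return float(self.group_tests.loc["reward", "t"])

    @property
    def interaction_t(self) -> float:
        return float(self.group_tests.loc["reward_x_transition", "t"])


_CELLS = [
    ("rewarded", "common"),
    ("rewarded", "rare"),
    ("unrewarded", "common"),
    ("unrewarded", "rare"),
]


def _stay_design(trials: pd.DataFrame) -> pd.DataFrame:
    """Stay indicator plus previous-trial predictors, within session."""
    parts = []
    for (sid, sess), grp in trials.groupby(["subject_id", "session"], sort=True):
        grp = grp.sort_values("trial")
        if len(grp) < 2:
            continue
        c1 = grp["choice1"].to_numpy()
        stay = (c1[1:] == c1[:-1]).astype(float)
        prev_r = grp["reward"].to_numpy()[:-1]
        prev_common = (grp["transition"].to_numpy()[:-1] == "common").astype(int)
        parts.append(pd.DataFrame({
            "subject_id": sid, "session": sess, "stay": stay,
            "prev_reward": prev_r, "prev_common": prev_common,
        }))
    if not parts:
        raise ValueError("no subject-session has >= 2 trials")
    return pd.concat(parts, ignore_index=True)


def stay_probability_analysis(trials: pd.DataFrame) -> StayTable:
    """First-stage choice-repetition analysis in the reward x transition design.

    A model-free controller repeats rewarded actions regardless of
    transition (reward main effect); a model-based controller repeats a
    rewarded action only when the reward arrived via a common transition
    (reward x transition interaction). Both predictors are effect coded
    (+0.5 rewarded / common, -0.5 otherwise). Subject-sessions with
    fewer than 2 trials are excluded with a warning.
    """
    short = [
        f"{sid}/{sess}"
        for (sid, sess), grp in trials.groupby(["subject_id", "session"])
        if len(grp) < 2
    ]
    if short:
        warnings.warn(f"excluding subject-sessions with < 2 trials: {short}")
    design = _stay_design(trials)

    prop_rows, coef_rows = [], []
    for sid, grp in design.groupby("subject_id", sort=True):
        row: dict = {"subject_id": sid}
        for rew_label, trans_label in _CELLS:
            mask = (grp["prev_reward"] == (rew_label == "rewarded")) & (
                grp["prev_common"] == (trans_label == "common")
            )
            row[f"{rew_label}_{trans_label}"] = (
                float(grp.loc[mask, "stay"].mean()) if mask.any() else np.nan
            )
        prop_rows.append(row)

        x_r = grp["prev_reward"].to_numpy() - 0.5
        x_t = grp["prev_common"].to_numpy() - 0.5
        X = np.column_stack([np.ones(len(grp)), x_r, x_t, x_r * x_t])
        y = grp["stay"].to_numpy()
        coef, ok = _subject_logistic(y, X)
        coef_rows.append({
            "subject_id": sid, "intercept": coef[0], "reward": coef[1],
            "transition": coef[2], "reward_x_transition": coef[3], "converged": ok,
        })

    cell_props = pd.DataFrame(prop_rows).set_index("subject_id")
    coefficients = pd.DataFrame(coef_rows).set_index("subject_id")

    tests = []
    used = coefficients[coefficients["converged"]]
    for term in ["intercept", "reward", "transition", "reward_x_transition"]:
        vals = used[term].to_numpy()
        mean = float(np.mean(vals))
        se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        t = mean / se if se and se > 0 else np.nan
        df = len(vals) - 1
        p = float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else np.nan
        tests.append({"term": term, "mean": mean, "se": se, "t": t, "df": df, "p_two": p})
    group_tests = pd.DataFrame(tests).set_index("term")

    return StayTable(
        cell_props=cell_props,
        group_means=cell_props.mean(),
        group_sems=cell_props.sem(),
        coefficients=coefficients,
        group_tests=group_tests,
        excluded=short,
    )


def _subject_logistic(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, bool]:
    """Per-subject logistic fit; flags separation / non-convergence."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=200)
            ok = bool(res.mle_retvals.get("converged", True)) and bool(
                np.all(np.abs(res.params) < 20)
            )
            return np.asarray(res.params, dtype=float), ok
        except Exception:
            return np.full(X.shape[1], np.nan), False


# ---------------------------------------------------------------------------
# repeated-measures interaction models
# ---------------------------------------------------------------------------

def _mixed_interaction(
    outcome: np.ndarray,
    x_cont: np.ndarray,
    x_factor: np.ndarray,
    subject: np.ndarray,
    direction: int,
) -> EffectResult:
    """Random-intercept mixed model outcome ~ x_cont * x_factor.

    Returns the interaction term. p-values use a t reference with
    residual degrees of freedom. On a singular / non-converged fit, falls
    back to subject-demeaned OLS (the within-subject projection), with a
    note in the result.
    """
    X = pd.DataFrame({
        "intercept": 1.0, "x": x_cont, "factor": x_factor, "x_by_factor": x_cont * x_factor,
    })
    notes = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(outcome, X, groups=subject)
            res = md.fit(reml=True, method="lbfgs")
        if not res.converged or not np.isfinite(res.bse["x_by_factor"]):
            raise RuntimeError("mixed model did not converge")
        b = float(res.params["x_by_factor"])
        se = float(res.bse["x_by_factor"])
        df = float(len(outcome) - X.shape[1])
    except Exception:
        # within-subject fallback: demeaning removes the random intercept
        notes = "singular mixed fit; subject-demeaned OLS fallback"
        dm = pd.DataFrame({"y": outcome, "x": x_cont, "f": x_factor, "s": subject})
        for col in ["y", "x", "f"]:
            dm[col] = dm[col] - dm.groupby("s")[col].transform("mean")
        dm["xf"] = (x_cont * x_factor) - pd.Series(x_cont * x_factor).groupby(subject).transform("mean").to_numpy()
        fit = sm.OLS(dm["y"].to_numpy(),
                     dm[["x", "f", "xf"]].to_numpy()).fit()
        b, se = float(fit.params[2]), float(fit.bse[2])
        df = float(fit.df_resid)
    t = b / se if se > 0 else 0.0
    p_two, p_one = _t_pvalues(t, df, direction)
    return EffectResult(b=b, se=se, t=t, df=df, p_two=p_two, p_one=p_one, notes=notes)


def trait_by_system_interaction(
    mf_estimates: Sequence[float],
    mb_estimates: Sequence[float],
    trait: Sequence[float],
    direction: int = -1,
) -> EffectResult:
    """Does a trait relate more strongly to the model-based weight?

    Stacks each subject's model-free and model-based weight estimates,
    codes the system as a within-subject factor (MF = -0.5, MB = +0.5),
    and fits a random-intercept mixed model of the estimate on trait,
    system, and their interaction. The interaction coefficient tests
    whether the trait slope differs between systems (one-tailed per
    ``direction``).
    """
    mf, mb, tr = _complete_cases(mf_estimates, mb_estimates, trait)
    if mf.size < 3:
        raise ValueError("need at least 3 complete subjects")
    if np.std(tr) == 0:
        raise ValueError("trait has zero variance")
    n = mf.size
    outcome = np.concatenate([mf, mb])
    x_trait = np.concatenate([tr, tr])
    x_sys = np.concatenate([np.full(n, -0.5), np.full(n, +0.5)])
    subject = np.concatenate([np.arange(n), np.arange(n)])
    return _mixed_interaction(outcome, x_trait, x_sys, subject, direction)


def association_comparison(
    mb_estimates: Sequence[float],
    mws: Sequence[float],
    dsst: Sequence[float],
    direction: int = -1,
) -> EffectResult:
    """Do two traits associate differently with the model-based weight?

    Each subject's z-scored spontaneous mind-wandering and DSST scores
    are stacked as one repeated-measures outcome; predictors are the
    model-based weight, the effect-coded test factor (mws = -0.5,
    dsst = +0.5), and their interaction, with random intercepts per
    subject. The interaction tests whether the weight's association
    differs between the two scores.
    """
    mb, a, b_ = _complete_cases(mb_estimates, mws, dsst)
    if mb.size < 3:
        raise ValueError("need at least 3 complete subjects")
    if np.std(a) == 0 or np.std(b_) == 0:
        raise ValueError("a trait has zero variance")
    z = lambda v: (v - v.mean()) / v.std(ddof=1)
    n = mb.size
    outcome = np.concatenate([z(a), z(b_)])
    x_weight = np.concatenate([mb, mb])
    x_test = np.concatenate([np.full(n, -0.5), np.full(n, +0.5)])
    subject = np.concatenate([np.arange(n), np.arange(n)])
    return _mixed_interaction(outcome, x_weight, x_test, subject, direction)
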