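"""Treatment sensitivity: day x arm models, baseline contrasts, effect sizes.

For each marker (and for nightly sleep duration) a random-intercept LMM with
categorical day, treatment arm and their interaction as fixed effects is
fitted over the whole study (days -6..6). Each dosing day's estimated
marginal mean is contrasted against the average of the six predose marginal
means within the same arm; contrast p-values are Bonferroni-corrected over
the family of (dosing days x arms) contrasts of one model. Cohen's d
standardizes a contrast by the total SD, sqrt(sigma_b^2 + sigma_w^2), of the
same model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from patsy import PatsyError

from .lmm import (
    FitError,
    FTestResult,
    LmmFit,
    design_row,
    estimate_contrast,
    fit_lmm,
    type3_f_test,
)
from .repeatability import IccResult, icc

_TERMS = {
    "day": "C(study_day, Sum)",
    "treatment": "C(arm, Sum)",
    "day_treatment": "C(study_day, Sum):C(arm, Sum)",
}


@dataclass(frozen=True)
class ContrastResult:
    """One dosing day's change from the averaged predose level, per arm."""

    arm: str
    day: int
    estimate: float
    se: float
    df: float
    p_raw: float
    p_adj: float
    family_size: int


@dataclass(frozen=True)
class EffectSize:
    arm: str
    day: int
    d: float


def fit_treatment_model(
    table: pd.DataFrame,
    value_col: str = "value_bpm",
    subject_col: str = "subject_id",
) -> LmmFit:
    """REML fit of ``value ~ day * arm`` with a subject random intercept."""
    if table["arm"].nunique() < 2:
        raise FitError("both treatment arms must be present")
    if table["study_day"].nunique() < 2:
        raise FitError("at least two study days are required")
    formula = f"{value_col} ~ C(study_day, Sum) * C(arm, Sum)"
    return fit_lmm(table, formula, subject_col=subject_col)


def anova_table(fit: LmmFit) -> list[FTestResult]:
    """Type III F tests for day, treatment and day x treatment."""
    return [type3_f_test(fit, term) for term in _TERMS.values()]


def _marginal_row(fit: LmmFit, day: int, arm: str) -> np.ndarray:
    return design_row(fit, {"study_day": [day], "arm": [arm]})[0]


def baseline_contrasts(
    fit: LmmFit,
    predose_days: Sequence[int] = range(-6, 0),
    postdose_days: Sequence[int] = range(0, 7),
    arms: Sequence[str] = ("placebo", "active"),
    family_size: int | None = None,
) -> list[ContrastResult]:
    """Postdose-vs-averaged-predose contrasts with Bonferroni correction.

    For each arm and dosing day d the contrast puts weight +1 on day d's
    estimated marginal mean and -1/len(predose) on each predose day's,
    within the arm. The t reference uses the within-subject containment df.
    Contrasts whose day level is absent from the fit are omitted with a
    warning. ``family_size`` defaults to the number of contrasts attempted
    (days x arms).
    """
    fit.require_converged()
    predose_days = list(predose_days)
    postdose_days = list(postdose_days)
    m = family_size if family_size is not None else len(postdose_days) * len(arms)
    out: list[ContrastResult] = []
    for arm in arms:
        try:
            pre_rows = np.stack([_marginal_row(fit, d, arm) for d in predose_days])
        except (PatsyError, KeyError) as exc:
            warnings.warn(f"predose level missing for arm {arm!r}: {exc}")
            continue
        pre_mean_row = pre_rows.mean(axis=0)
        for d in postdose_days:
            try:
                c = _marginal_row(fit, d, arm) - pre_mean_row
            except (PatsyError, KeyError) as exc:
                warnings.warn(f"day {d} missing for arm {arm!r}; contrast omitted: {exc}")
                continue
            est, se = estimate_contrast(fit, c)
            if se == 0:
                p_raw = 0.0 if est != 0 else 1.0
            else:
                p_raw = float(2 * st.t.sf(abs(est) / se, fit.df_within))
            out.append(
                ContrastResult(arm, d, est, se, fit.df_within, p_raw, min(1.0, m * p_raw), m)
            )
    return out


def cohens_d(contrast: ContrastResult, fit: LmmFit) -> EffectSize:
    """Contrast standardized by the model's total SD, sqrt(s2_b + s2_w)."""
    fit.require_converged()
    total = fit.sigma2_total
    if total <= 0:
        raise ValueError("total variance is zero; effect size undefined")
    return EffectSize(contrast.arm, contrast.day, contrast.estimate / math.sqrt(total))


@dataclass(frozen=True)
class SleepModelResult:
    f_day: FTestResult
    f_treatment: FTestResult
    f_interaction: FTestResult
    icc: IccResult
    fit: LmmFit


def sleep_duration_model(durations: pd.DataFrame) -> SleepModelResult:
    """Day x treatment LMM for nightly sleep duration (detected nights only).

    ``durations`` needs columns subject_id, study_day, arm, duration_h.
    Returns the three type III F tests and the ICC of sleep duration.
    """
    fit = fit_treatment_model(durations, value_col="duration_h")
    tests = anova_table(fit)
    return SleepModelResult(tests[0], tests[1], tests[2], icc(fit), fit)


# -- tabular report helpers ------------------------------------------------


def contrasts_frame(
    results: dict[tuple[str, str], list[ContrastResult]], p_cap: float = 0.99
) -> pd.DataFrame:
    """Long contrast table over (period, marker) model families.

    ``p_display`` caps the adjusted p-value at ``p_cap`` for reporting; the
    exact Bonferroni value is kept in ``p_adj``.
    """
    rows = []
    for (period, marker), contrasts in results.items():
        for c in contrasts:
            rows.append(
                (
                    period,
                    marker,
                    c.arm,
                    c.day,
                    c.estimate,
                    c.se,
                    c.df,
                    c.p_raw,
                    c.p_adj,
                    min(c.p_adj, p_cap),
                    c.family_size,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "period",
            "marker",
            "arm",
            "day",
            "estimate_bpm",
            "se_bpm",
            "df",
            "p_raw",
            "p_adj",
            "p_display",
            "family_size",
        ],
    )


def effect_sizes_frame(results: dict[tuple[str, str], list[EffectSize]]) -> pd.DataFrame:
    rows = [
        (period, marker, e.arm, e.day, e.d)
        for (period, marker), effs in results.items()
        for e in effs
    ]
    return pd.DataFrame(rows, columns=["period", "marker", "arm", "day", "d"])


def anova_frame(results: dict[tuple[str, str], list[FTestResult]]) -> pd.DataFrame:
    name_of = {v: k for k, v in _TERMS.items()}
    rows = [
        (period, marker, name_of.get(f.term, f.term), f.statistic, f.df_num, f.df_den, f.p_value)
        for (period, marker), tests in results.items()
        for f in tests
    ]
    return pd.DataFrame(
        rows, columns=["period", "marker", "term", "F", "df_num", "df_den", "p"]
    )
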