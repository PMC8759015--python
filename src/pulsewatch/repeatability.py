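"""Predose repeatability of the HR markers: ICC, day effect, and MDE.

For each marker, a random-intercept LMM with categorical study day as the
only fixed factor is fitted to the predose data (days -6..-1). Repeatability
is the intraclass correlation coefficient

    ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2),

the ratio of the between-subject variance to the total variance. Structural
day-to-day variability is assessed with the type III F test of the day
factor. The minimum detectable effect (MDE) converts the total SD into the
smallest true difference detectable at significance level alpha and the
given power by an inverse sample-size calculation with t-quantiles at n-1
degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
import scipy.stats as st

from .config import AnalysisOptions
from .lmm import FitError, FTestResult, LmmFit, fit_lmm, type3_f_test

DAY_TERM = "C(study_day, Sum)"


@dataclass(frozen=True)
class IccResult:
    icc: float
    sigma2_b: float
    sigma2_w: float


@dataclass(frozen=True)
class MdeResult:
    mde_bpm: float
    mde_pct: float | None  # relative to the model-estimated marker mean
    sd_total_bpm: float
    n: int
    alpha: float
    power: float
    form: str


def fit_random_intercept(
    table: pd.DataFrame,
    value_col: str = "value_bpm",
    day_col: str = "study_day",
    subject_col: str = "subject_id",
) -> LmmFit:
    """REML fit of ``value ~ intercept + day`` with a subject random intercept.

    ``table`` is one marker's long slice; unbalanced data are allowed.
    """
    if table[day_col].nunique() < 2:
        raise FitError("at least two study days are required")
    formula = f"{value_col} ~ C({day_col}, Sum)"
    return fit_lmm(table, formula, subject_col=subject_col)


def icc(fit: LmmFit) -> IccResult:
    """Intraclass correlation from a converged fit, clamped to [0, 1]."""
    fit.require_converged()
    total = fit.sigma2_b + fit.sigma2_w
    if total <= 0:
        raise ValueError("total variance is zero; ICC undefined")
    return IccResult(min(max(fit.sigma2_b / total, 0.0), 1.0), fit.sigma2_b, fit.sigma2_w)


def day_f_test(fit: LmmFit) -> FTestResult:
    """Type III F test of the study-day factor (numerator df = levels - 1)."""
    day_terms = [t for t in fit.term_cols if "study_day" in t and ":" not in t]
    if not day_terms:
        raise FitError("model has no study-day factor")
    return type3_f_test(fit, day_terms[0])


def mde(
    sd_total_bpm: float,
    n: int = 12,
    alpha: float = 0.05,
    power: float = 0.80,
    form: str = "two_sample",
    mean_bpm: float | None = None,
) -> MdeResult:
    """Minimum detectable effect via the inverse sample-size calculation.

    ``MDE = (t_{1-alpha/2, n-1} + t_{power, n-1}) * sd_total * f(n)`` with
    ``f(n) = sqrt(2/n)`` for the two-sample (parallel-group) form and
    ``sqrt(1/n)`` for the paired form. ``mde_pct`` is reported relative to
    ``mean_bpm`` when given.
    """
    if sd_total_bpm < 0:
        raise ValueError("sd_total_bpm must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2 (t-quantiles need n-1 >= 1 df)")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    if form not in ("two_sample", "paired"):
        raise ValueError("form must be 'two_sample' or 'paired'")
    t_alpha = st.t.ppf(1 - alpha / 2, n - 1)
    t_power = st.t.ppf(power, n - 1)
    factor = math.sqrt((2.0 if form == "two_sample" else 1.0) / n)
    mde_bpm = (t_alpha + t_power) * sd_total_bpm * factor
    mde_pct = None if mean_bpm is None else 100.0 * mde_bpm / mean_bpm
    return MdeResult(mde_bpm, mde_pct, sd_total_bpm, n, alpha, power, form)


def repeatability_table(
    marker_table: pd.DataFrame, options: AnalysisOptions = AnalysisOptions()
) -> pd.DataFrame:
    """Per-marker predose repeatability summary (one row per period x marker).

    Columns: period, marker, mean_bpm (estimated marginal mean = intercept of
    the sum-coded model), se, icc, mde_bpm, mde_pct, f_day, df_num, df_den,
    p_day.
    """
    pre = marker_table[marker_table["study_day"].isin(options.predose)]
    rows = []
    for (period, marker), grp in pre.groupby(["period", "marker"], sort=True):
        fit = fit_random_intercept(grp)
        r_icc = icc(fit)
        f = day_f_test(fit)
        mean = float(fit.params.iloc[0])  # sum-coded intercept = grand marginal mean
        se = float(fit.cov_fe.iloc[0, 0]) ** 0.5
        r_mde = mde(
            math.sqrt(fit.sigma2_total),
            n=options.mde_n,
            alpha=options.alpha,
            power=options.power,
            form=options.mde_form,
            mean_bpm=mean,
        )
        rows.append(
            (
                period,
                marker,
                mean,
                se,
                r_icc.icc,
                r_mde.mde_bpm,
                r_mde.mde_pct,
                f.statistic,
                f.df_num,
                f.df_den,
                f.p_value,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "period",
            "marker",
            "mean_bpm",
            "se",
            "icc",
            "mde_bpm",
            "mde_pct",
            "f_day",
            "df_num",
            "df_den",
            "p_day",
        ],
    )
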