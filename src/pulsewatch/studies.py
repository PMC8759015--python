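"""Replicate parameter-recovery studies on synthetic data.

Because the trial's device data are not public, the pipeline is validated by
simulating many replicate studies at the trial's scale (12 subjects, 4:8
placebo:active, 6 predose + 7 treatment days) with known generating
parameters and checking that the estimators recover them: ICC of markers and
sleep duration, Cohen's d of an injected shift, the family-wise error of the
Bonferroni-corrected contrasts, and the generator's sampling calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ingest
from .config import GeneratorConfig
from .lmm import FitError
from .repeatability import fit_random_intercept, icc
from .synthetic import simulate_cohort, simulate_marker_table
from .treatment import baseline_contrasts, cohens_d, fit_treatment_model, sleep_duration_model


@dataclass(frozen=True)
class RecoveryResult:
    name: str
    truth: float
    mean_estimate: float
    sd_estimate: float
    n_replicates: int

    @property
    def se(self) -> float:
        return self.sd_estimate / np.sqrt(self.n_replicates)


def _child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def icc_marker_recovery(
    sigma2_b: float,
    sigma2_w: float,
    n_subjects: int = 12,
    days: range = range(-6, 0),
    n_replicates: int = 200,
    seed: int = 0,
    mu: float = 63.2,
) -> RecoveryResult:
    """Mean pipeline ICC over replicate predose marker tables."""
    truth = sigma2_b / (sigma2_b + sigma2_w)
    est = []
    for ss in _child_seeds(seed, n_replicates):
        tab = simulate_marker_table(
            n_subjects, days, np.sqrt(sigma2_b), np.sqrt(sigma2_w), ss, mu=mu
        )
        est.append(icc(fit_random_intercept(tab)).icc)
    est = np.asarray(est)
    return RecoveryResult(
        f"icc[{truth:.2f}]", truth, float(est.mean()), float(est.std(ddof=1)), n_replicates
    )


def sleep_icc_recovery(
    sigma_b_h: float = 0.8,
    sigma_w_h: float = 0.6,
    n_subjects: int = 12,
    days: range = range(-6, 7),
    n_replicates: int = 200,
    seed: int = 0,
    mean_h: float = 6.5,
) -> RecoveryResult:
    """Mean sleep-duration ICC from the day x treatment model, no true effect."""
    truth = sigma_b_h**2 / (sigma_b_h**2 + sigma_w_h**2)
    est = []
    for ss in _child_seeds(seed, n_replicates):
        tab = simulate_marker_table(
            n_subjects, days, sigma_b_h, sigma_w_h, ss, mu=mean_h, value_col="duration_h"
        )
        est.append(sleep_duration_model(tab).icc.icc)
    est = np.asarray(est)
    return RecoveryResult(
        "icc[sleep]", truth, float(est.mean()), float(est.std(ddof=1)), n_replicates
    )


def effect_size_recovery(
    shift_bpm: float = 16.18,
    shift_day: int = 3,
    sigma2_b: float = 24.01,
    sigma2_w: float = 10.63,
    n_subjects: int = 12,
    days: range = range(-6, 7),
    n_replicates: int = 200,
    seed: int = 0,
    mu: float = 63.2,
) -> RecoveryResult:
    """Mean estimated Cohen's d for an injected active-arm shift on one day."""
    truth = shift_bpm / np.sqrt(sigma2_b + sigma2_w)
    fixed = {(shift_day, "active"): shift_bpm}
    est = []
    for ss in _child_seeds(seed, n_replicates):
        tab = simulate_marker_table(
            n_subjects, days, np.sqrt(sigma2_b), np.sqrt(sigma2_w), ss, mu=mu, fixed_effects=fixed
        )
        fit = fit_treatment_model(tab)
        contrasts = baseline_contrasts(fit)
        (c,) = [x for x in contrasts if x.arm == "active" and x.day == shift_day]
        est.append(cohens_d(c, fit).d)
    est = np.asarray(est)
    return RecoveryResult(
        f"cohens_d[day {shift_day}]", truth, float(est.mean()), float(est.std(ddof=1)), n_replicates
    )


def familywise_error_rate(
    n_replicates: int = 500,
    alpha: float = 0.05,
    n_subjects: int = 12,
    days: range = range(-6, 7),
    sigma2_b: float = 24.01,
    sigma2_w: float = 10.63,
    seed: int = 0,
    mu: float = 63.2,
) -> RecoveryResult:
    """Fraction of null replicates with any Bonferroni-adjusted p < alpha."""
    hits = 0
    done = 0
    for ss in _child_seeds(seed, n_replicates):
        tab = simulate_marker_table(
            n_subjects, days, np.sqrt(sigma2_b), np.sqrt(sigma2_w), ss, mu=mu
        )
        try:
            fit = fit_treatment_model(tab)
            contrasts = baseline_contrasts(fit)
        except FitError:
            continue
        done += 1
        if any(c.p_adj < alpha for c in contrasts):
            hits += 1
    rate = hits / max(done, 1)
    return RecoveryResult("familywise_error", alpha, rate, float(np.sqrt(rate * (1 - rate))), done)


@dataclass(frozen=True)
class SamplingCalibration:
    mean_asleep_per_day: float
    mean_awake_per_day: float
    n_patient_days: int


def sampling_calibration(
    min_patient_days: int = 1000, seed: int = 0, config: GeneratorConfig | None = None
) -> SamplingCalibration:
    """Per-patient-day asleep/awake sample counts through the real pipeline.

    Cohorts are simulated at the default configuration until at least
    ``min_patient_days`` study days with a detected night (and sleep-bounded
    awake window) have accumulated; counts come from the segmentation stage,
    i.e. they are the sample sizes the markers actually summarize.
    """
    base = config or GeneratorConfig()
    asleep_counts: list[int] = []
    awake_counts: list[int] = []
    total_days = 0
    rep = 0
    while total_days < min_patient_days:
        cfg = base.with_seed(int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % 2**31))
        hr, sleep, allocation, _ = simulate_cohort(cfg)
        intervals = ingest.nightly_intervals(sleep, allocation, cfg.days)
        segments = ingest.segment_cohort(hr, intervals, allocation)
        for seg in segments:
            total_days += 1
            if seg.asleep_samples is not None:
                asleep_counts.append(len(seg.asleep_samples))
            if seg.awake_window_source == "sleep_bounds":
                awake_counts.append(len(seg.awake_samples))
        rep += 1
    return SamplingCalibration(
        float(np.mean(asleep_counts)), float(np.mean(awake_counts)), total_days
    )
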