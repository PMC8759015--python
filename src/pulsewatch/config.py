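"""Configuration objects for the synthetic cohort generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Tuple


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


#: True active-arm shift (bpm) per (study day, period), used as the generator
#: default treatment effect. Calibrated to the published post-hoc contrasts of
#: the clenbuterol arm (asleep/awake median markers): onset on the first
#: treatment night, plateau once the 80 ug dose is reached.
DEFAULT_EFFECT_PROFILE_BPM: Mapping[Tuple[int, str], float] = {
    (0, "asleep"): 3.7,
    (1, "asleep"): 7.90,
    (2, "asleep"): 11.87,
    (3, "asleep"): 16.18,
    (4, "asleep"): 13.45,
    (5, "asleep"): 15.48,
    (6, "asleep"): 15.18,
    (0, "awake"): 1.79,
    (1, "awake"): 5.10,
    (2, "awake"): 10.79,
    (3, "awake"): 14.54,
    (4, "awake"): 16.35,
    (5, "awake"): 11.41,
    (6, "awake"): 12.22,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters of the simulated smartwatch trial.

    Defaults emulate the parallel-group design that motivates this package:
    12 subjects randomized placebo:active 1:2, a 6-day baseline (days -6..-1)
    and a 7-day treatment period (days 0..6) with the beta2-agonist dose
    titrated 20 -> 40 -> 80 ug over the first three dosing days.

    HR model per sample (bpm):

        hr(t) = mu_period + b_i + eps_{i,day,period} + circadian(t)
                + effect(day, period) [active arm] + burst(t) + noise

    with ``b_i ~ N(0, sigma_b^2)`` a subject random intercept,
    ``eps`` a day-level deviation ``N(0, sigma_w^2)`` shared by all samples of
    one subject-day-period cell, and ``noise ~ N(0, sigma_sample^2)`` per
    sample. Nights start around ``sleep_onset_mean_clock`` and last
    ``N(sleep_duration_mean_h, sleep_duration_sd_h)`` hours; the watch samples
    HR every ``base_sampling_min`` minutes and tightens to
    ``burst_sampling_min`` during daytime activity bursts.
    """

    n_subjects: int = 12
    allocation_ratio: Tuple[int, int] = (1, 2)  # placebo : active
    study_days: Tuple[int, int] = (-6, 6)  # inclusive range
    dose_schedule_ug: Tuple[float, ...] = (20, 40, 80, 80, 80, 80, 80)
    effect_profile_bpm: Mapping[Tuple[int, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_PROFILE_BPM)
    )
    mu_awake_bpm: float = 75.4
    mu_asleep_bpm: float = 63.2
    sigma_b_bpm: float = 4.9
    sigma_w_bpm: float = 3.3
    sigma_sample_bpm: float = 6.0
    circadian_amp_bpm: float = 3.0
    circadian_phase_h: float = 15.0  # clock hour of the circadian HR peak
    sleep_onset_mean_clock: str = "23:30"
    sleep_onset_sd_min: float = 45.0
    sleep_duration_mean_h: float = 6.5
    sleep_duration_sd_h: float = 0.6  # night-to-night (within-subject) SD
    sleep_duration_subject_sd_h: float = 0.8  # between-subject SD of habitual duration
    base_sampling_min: float = 10.0
    activity_bursts_per_day: int = 1
    burst_len_min: float = 12.0
    burst_sampling_min: float = 1.0
    burst_elevation_bpm: float = 28.0
    p_missing_sleep_states: float = 0.1
    p_short_night: float = 0.02
    anchor_date: str = "2021-03-01"  # calendar date of study day 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if min(self.allocation_ratio) < 0 or sum(self.allocation_ratio) <= 0:
            raise ConfigError("allocation_ratio must be non-negative, not both zero")
        if self.study_days[0] > self.study_days[1]:
            raise ConfigError("study_days range is empty")
        for name in (
            "sigma_b_bpm",
            "sigma_w_bpm",
            "sigma_sample_bpm",
            "circadian_amp_bpm",
            "sleep_onset_sd_min",
            "sleep_duration_sd_h",
            "sleep_duration_subject_sd_h",
            "burst_elevation_bpm",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("p_missing_sleep_states", "p_short_night"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.sleep_duration_mean_h <= 0:
            raise ConfigError("sleep_duration_mean_h must be > 0")
        if self.base_sampling_min <= 0 or self.burst_sampling_min <= 0:
            raise ConfigError("sampling cadences must be > 0")
        titration = self.dose_schedule_ug[: min(3, len(self.dose_schedule_ug))]
        if any(b < a for a, b in zip(titration, titration[1:])):
            raise ConfigError("dose schedule must be non-decreasing over titration days")
        try:
            h, m = self.sleep_onset_mean_clock.split(":")
            int(h), int(m)
        except Exception as exc:  # pragma: no cover - message only
            raise ConfigError("sleep_onset_mean_clock must be 'HH:MM'") from exc

    # -- derived quantities -------------------------------------------------

    @property
    def n_placebo(self) -> int:
        p, a = self.allocation_ratio
        return int(round(self.n_subjects * p / (p + a)))

    @property
    def days(self) -> range:
        return range(self.study_days[0], self.study_days[1] + 1)

    @property
    def sleep_onset_hour(self) -> float:
        h, m = self.sleep_onset_mean_clock.split(":")
        return int(h) + int(m) / 60.0

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class AnalysisOptions:
    """Statistical constants of the analysis stage.

    ``mde_form`` selects the inverse sample-size formula: ``"two_sample"``
    uses the parallel-group difference factor sqrt(2/n) (default, matching a
    two-arm trial), ``"paired"`` uses sqrt(1/n).
    """

    alpha: float = 0.05
    power: float = 0.80
    mde_form: str = "two_sample"
    mde_n: int = 12
    predose_days: Tuple[int, int] = (-6, -1)  # inclusive
    postdose_days: Tuple[int, int] = (0, 6)  # inclusive
    bonferroni_family: int | None = None  # None -> n_postdose_days * n_arms
    percentile_method: str = "linear"  # interpolation between closest ranks
    p_display_cap: float = 0.99

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ConfigError("power must be in (0, 1)")
        if self.mde_form not in ("two_sample", "paired"):
            raise ConfigError("mde_form must be 'two_sample' or 'paired'")
        if self.predose_days[1] >= self.postdose_days[0]:
            raise ConfigError("predose range must precede the first dosing day")

    @property
    def predose(self) -> Sequence[int]:
        return range(self.predose_days[0], self.predose_days[1] + 1)

    @property
    def postdose(self) -> Sequence[int]:
        return range(self.postdose_days[0], self.postdose_days[1] + 1)
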