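import numpy as np
import pandas as pd
import pytest

from pulsewatch.config import GeneratorConfig
from pulsewatch.synthetic import SubjectState, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort shared by read-only tests."""
    cfg = GeneratorConfig(seed=7)
    hr, sleep, allocation, truth = simulate_cohort(cfg)
    allocation = allocation.assign(anchor_date=pd.to_datetime(allocation["anchor_date"]))
    return cfg, hr, sleep, allocation, truth


@pytest.fixture()
def quiet_subject():
    """A single active-arm subject with all random components zeroed."""
    cfg = GeneratorConfig(
        sigma_b_bpm=0.0,
        sigma_w_bpm=0.0,
        sigma_sample_bpm=0.0,
        circadian_amp_bpm=0.0,
        sleep_onset_sd_min=0.0,
        sleep_duration_sd_h=0.0,
        sleep_duration_subject_sd_h=0.0,
        p_missing_sleep_states=0.0,
        p_short_night=0.0,
        effect_profile_bpm={},
        seed=0,
    )
    return SubjectState("S01", "active", 0.0, 0.0, pd.Timestamp("2021-03-01"), cfg)


def sorting_percentile_oracle(values, p):
    """Independent linear-interpolation percentile: sort, h=(n-1)p, lerp."""
    xs = sorted(float(v) for v in values)
    h = (len(xs) - 1) * p
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def anova_mom_oracle(table, value_col="value_bpm"):
    """Balanced two-way (subject + day) method-of-moments variance components.

    sigma_w^2 = MSW (residual mean square after subject and day means);
    sigma_b^2 = (MSB - MSW) / k with k days per subject.
    """
    n = table["subject_id"].nunique()
    k = table["study_day"].nunique()
    smeans = table.groupby("subject_id")[value_col].mean()
    dmeans = table.groupby("study_day")[value_col].mean()
    grand = table[value_col].mean()
    msb = k * ((smeans - grand) ** 2).sum() / (n - 1)
    resid = (
        table[value_col]
        - table["subject_id"].map(smeans)
        - table["study_day"].map(dmeans)
        + grand
    )
    msw = (resid**2).sum() / ((n - 1) * (k - 1))
    return (msb - msw) / k, msw
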