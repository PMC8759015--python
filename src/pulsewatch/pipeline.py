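"""End-to-end orchestration: raw streams -> the five report tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import ingest, markers, repeatability, treatment
from .config import AnalysisOptions

log = logging.getLogger("pulsewatch")


@dataclass
class Report:
    """The pipeline's output tables plus run accounting."""

    repeatability: pd.DataFrame
    anova: pd.DataFrame
    contrasts: pd.DataFrame
    effect_sizes: pd.DataFrame
    sleep_model: pd.DataFrame
    marker_table: pd.DataFrame
    sleep_durations: pd.DataFrame
    night_accounting: Mapping[str, int] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in (
            "repeatability",
            "anova",
            "contrasts",
            "effect_sizes",
            "sleep_model",
            "marker_table",
            "sleep_durations",
        ):
            paths[name] = out / f"{name}.csv"
            getattr(self, name).to_csv(paths[name], index=False, float_format="%.6g")
        return paths


def run_pipeline(
    hr: pd.DataFrame,
    sleep: pd.DataFrame,
    allocation: pd.DataFrame,
    days: range,
    options: AnalysisOptions = AnalysisOptions(),
) -> Report:
    """Segment, summarize and model a cohort's raw streams.

    ``days`` is the study-day range to analyze (e.g. range(-6, 7)).
    """
    intervals = ingest.nightly_intervals(sleep, allocation, days)
    accounting = dict(ingest.night_accounting(intervals))
    log.info(
        "nights: %d detected, %d excluded (<3 h), %d missing sleep states",
        accounting["detected"],
        accounting["excluded_short"],
        accounting["missing"],
    )
    segments = ingest.segment_cohort(hr, intervals, allocation)
    marker_table = markers.build_marker_table(segments, allocation)
    log.info("marker table: %d rows", len(marker_table))

    durations = ingest.sleep_duration_table(intervals).merge(
        allocation[["subject_id", "arm"]], on="subject_id"
    )

    rep = repeatability.repeatability_table(marker_table, options)

    anova_res: dict[tuple[str, str], list] = {}
    contrast_res: dict[tuple[str, str], list] = {}
    effect_res: dict[tuple[str, str], list] = {}
    for (period, marker), grp in marker_table.groupby(["period", "marker"], sort=True):
        fit = treatment.fit_treatment_model(grp).require_converged()
        anova_res[(period, marker)] = treatment.anova_table(fit)
        contrasts = treatment.baseline_contrasts(
            fit,
            predose_days=options.predose,
            postdose_days=options.postdose,
            family_size=options.bonferroni_family,
        )
        contrast_res[(period, marker)] = contrasts
        effect_res[(period, marker)] = [treatment.cohens_d(c, fit) for c in contrasts]

    sleep_res = treatment.sleep_duration_model(durations)
    sleep_model = pd.DataFrame(
        [
            ("day", sleep_res.f_day.statistic, sleep_res.f_day.df_num, sleep_res.f_day.df_den, sleep_res.f_day.p_value),
            (
                "treatment",
                sleep_res.f_treatment.statistic,
                sleep_res.f_treatment.df_num,
                sleep_res.f_treatment.df_den,
                sleep_res.f_treatment.p_value,
            ),
            (
                "day_treatment",
                sleep_res.f_interaction.statistic,
                sleep_res.f_interaction.df_num,
                sleep_res.f_interaction.df_den,
                sleep_res.f_interaction.p_value,
            ),
            ("icc", sleep_res.icc.icc, None, None, None),
        ],
        columns=["term", "value", "df_num", "df_den", "p"],
    )

    return Report(
        repeatability=rep,
        anova=treatment.anova_frame(anova_res),
        contrasts=treatment.contrasts_frame(contrast_res, p_cap=options.p_display_cap),
        effect_sizes=treatment.effect_sizes_frame(effect_res),
        sleep_model=sleep_model,
        marker_table=marker_table,
        sleep_durations=durations,
        night_accounting=accounting,
    )
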