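"""End-to-end analysis pipeline: raw cohort -> QC -> summary tables -> inference.

Mirrors the study workflow: per-task block QC and threshold aggregation,
per-participant tapping summaries, a wide per-participant cohort table, and
the group-level statistics (normality screen, ANOVA with generalised eta
squared, Tukey HSD, Levene, cross-task correlations, and the two-covariate
ANCOVA).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from delaydetect.config import ANISOCHRONY_TASK, DELAY_TASK
from delaydetect.inference import (
    ancova_two_covariates,
    correlate,
    homogeneity_test,
    normality_screen,
    oneway_anova_ges,
    tukey_hsd,
)
from delaydetect.observers import Cohort
from delaydetect.qc import aggregate_thresholds
from delaydetect.tapping import participant_tapping_stats

__all__ = ["qc_cohort", "tapping_table", "cohort_table", "analyze_cohort"]

_TASK_CUTOFFS = {"delay": DELAY_TASK.slope_cutoff,
                 "anisochrony": ANISOCHRONY_TASK.slope_cutoff}


def qc_cohort(cohort: Cohort) -> pd.DataFrame:
    """Apply both QC rules and aggregate per-participant thresholds.

    One row per participant x task that retains at least one block;
    participants whose blocks all fail a task's QC are absent for that task.
    """
    rows = []
    for p in cohort.participants:
        for task, session in (("delay", p.delay_session),
                              ("anisochrony", p.aniso_session)):
            if session is None:
                continue
            agg = aggregate_thresholds(session.experimental, p.participant_id,
                                       task, _TASK_CUTOFFS[task])
            if agg is not None:
                rows.append({
                    "participant_id": p.participant_id,
                    "group": p.group,
                    "task": task,
                    "retained_blocks": agg.retained_block_count,
                    "threshold_ms": agg.threshold,
                    "log_threshold": agg.log_threshold,
                })
    return pd.DataFrame(rows, columns=["participant_id", "group", "task",
                                       "retained_blocks", "threshold_ms",
                                       "log_threshold"])


def tapping_table(cohort: Cohort) -> pd.DataFrame:
    """Per-participant tapping summary (block statistics averaged)."""
    rows = []
    for p in cohort.participants:
        if not p.tap_records:
            continue
        stats_ = participant_tapping_stats(p.tap_records)
        stats_.update(participant_id=p.participant_id, group=p.group)
        rows.append(stats_)
    frame = pd.DataFrame(rows)
    lead = ["participant_id", "group"]
    return frame[lead + [c for c in frame.columns if c not in lead]]


def cohort_table(thresholds: pd.DataFrame,
                 tapping: pd.DataFrame) -> pd.DataFrame:
    """Wide per-participant table feeding group-level inference.

    Columns: group, per-task thresholds (ms and natural log) and the
    tapping measures.  Rows are participants; task columns are NaN where a
    participant lost all blocks of that task to QC.
    """
    wide = thresholds.pivot(index=["participant_id", "group"], columns="task",
                            values="log_threshold").reset_index()
    wide = wide.rename(columns={"delay": "log_delay_threshold",
                                "anisochrony": "log_aniso_threshold"})
    ms = thresholds.pivot(index=["participant_id", "group"], columns="task",
                          values="threshold_ms").reset_index()
    ms = ms.rename(columns={"delay": "delay_threshold_ms",
                            "anisochrony": "aniso_threshold_ms"})
    wide = wide.merge(ms, on=["participant_id", "group"], how="outer")
    tap = tapping.rename(columns={"vector_z": "sync_vector_z",
                                  "vector_length_r": "sync_vector_r"})
    out = wide.merge(tap, on=["participant_id", "group"], how="outer")
    for col in ("log_delay_threshold", "log_aniso_threshold",
                "delay_threshold_ms", "aniso_threshold_ms"):
        if col not in out:
            out[col] = np.nan
    return out


def analyze_cohort(cohort: Cohort) -> dict:
    """Full group-level report for a generated cohort.

    Returns a nested dict with the QC'd tables and every statistic: per-task
    normality screens (raw and log thresholds), ANOVAs with generalised eta
    squared, Tukey HSD post-hocs, Levene tests, cross-task correlations,
    and the two-covariate ANCOVA on the log delay threshold.
    """
    thresholds = qc_cohort(cohort)
    tapping = tapping_table(cohort)
    table = cohort_table(thresholds, tapping)
    report: dict = {"tables": {"thresholds": thresholds, "tapping": tapping,
                               "cohort": table}}

    for task, col in (("delay", "log_delay_threshold"),
                      ("anisochrony", "log_aniso_threshold")):
        sub = table.dropna(subset=[col])
        raw = np.exp(sub[col].to_numpy(dtype=float))
        entry = {
            "n": len(sub),
            "normality_raw": normality_screen(raw),
            "normality_log": normality_screen(sub[col]),
            "anova": oneway_anova_ges(sub, col, "group"),
            "tukey": tukey_hsd(sub, col, "group"),
            "levene": homogeneity_test(sub, col, "group"),
        }
        report[task] = entry

    complete = table.dropna(subset=["log_delay_threshold",
                                    "log_aniso_threshold", "sync_vector_z"])
    report["correlations"] = {
        "delay_vs_aniso": correlate(complete, "log_delay_threshold",
                                    "log_aniso_threshold"),
        "delay_vs_sync": correlate(complete, "log_delay_threshold",
                                   "sync_vector_z"),
    }
    report["ancova"] = ancova_two_covariates(complete)
    return report
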