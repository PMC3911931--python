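"""CSV/JSON serialisation of sessions, tap logs and analysis tables.

Trial logs use one row per trial with the schema::

    participant_id, group, task, block_index, trial_index, is_catch,
    proposed_level_ms, presented_level_ms, response, ml_midpoint_ms, ml_fa

Block index -1 is the practice log, 0 the training block, 1..3 the
experimental blocks.  Tap logs are long-format event tables::

    participant_id, block, phase, event_time_ms, event_type

with phase in {sync, continuation} and event_type in {tap, click}.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from delaydetect.mlp import BlockResult, Trial
from delaydetect.observers import Cohort, Participant
from delaydetect.protocols import SessionResult
from delaydetect.tapping import TapRecord

__all__ = [
    "session_frame",
    "tap_frame",
    "write_cohort",
    "read_trial_logs",
    "read_tap_logs",
    "tap_records_from_frame",
]

TRIAL_COLUMNS = ["participant_id", "group", "task", "block_index",
                 "trial_index", "is_catch", "proposed_level_ms",
                 "presented_level_ms", "response", "ml_midpoint_ms", "ml_fa"]
TAP_COLUMNS = ["participant_id", "block", "phase", "event_time_ms",
               "event_type"]


def _trial_rows(trials, participant_id, group, task, block_index):
    for t in trials:
        yield {
            "participant_id": participant_id, "group": group, "task": task,
            "block_index": block_index, "trial_index": t.index,
            "is_catch": int(t.is_catch),
            "proposed_level_ms": t.proposed_level,
            "presented_level_ms": t.presented_level,
            "response": t.response,
            "ml_midpoint_ms": t.ml_midpoint, "ml_fa": t.ml_fa,
        }


def session_frame(session: SessionResult, participant_id: str,
                  group: str) -> pd.DataFrame:
    """Flatten one session (practice, training, experimental) to a trial log."""
    rows = list(_trial_rows(session.practice, participant_id, group,
                            session.task, -1))
    rows += list(_trial_rows(session.training.trials, participant_id, group,
                             session.task, 0))
    for b, block in enumerate(session.experimental, start=1):
        rows += list(_trial_rows(block.trials, participant_id, group,
                                 session.task, b))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def tap_frame(records, participant_id: str) -> pd.DataFrame:
    """Long-format event table for a participant's tapping blocks."""
    rows = []
    for b, rec in enumerate(records, start=1):
        for t in rec.metronome_onsets:
            rows.append((participant_id, b, "sync", float(t), "click"))
        for t in rec.sync_taps:
            rows.append((participant_id, b, "sync", float(t), "tap"))
        for t in rec.continuation_taps:
            rows.append((participant_id, b, "continuation", float(t), "tap"))
    return pd.DataFrame(rows, columns=TAP_COLUMNS)


def write_session(session: SessionResult, participant_id: str, group: str,
                  out_dir) -> Path:
    """Write one session as ``<id>_<task>.csv`` plus a manifest JSON with
    the task config, seed and per-block QC verdicts (where annotated)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{participant_id}_{session.task}"
    session_frame(session, participant_id, group).to_csv(
        out / f"{stem}.csv", index=False)
    manifest = {
        "participant_id": participant_id,
        "group": group,
        "task": session.task,
        "seed": session.seed,
        "config": session.config.to_dict(),
        "blocks": [
            {"block_index": i, "final_threshold": b.final_threshold,
             "catch_error_rate": b.catch_error_rate,
             "convergence_slope": b.convergence_slope,
             "retained": b.retained, "aborted": b.aborted}
            for i, b in enumerate(session.experimental, start=1)
        ],
    }
    (out / f"{stem}_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out / f"{stem}.csv"


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a cohort as per-participant CSV logs plus a summary.

    Layout: ``<out>/trials.csv`` (all sessions), ``<out>/taps.csv`` (all
    tapping blocks), ``<out>/cohort.csv`` (ground-truth summary) and
    ``<out>/manifest.json`` (seed and generator config).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trial_frames, tap_frames, truth_rows = [], [], []
    for p in cohort.participants:
        for session in (p.delay_session, p.aniso_session):
            if session is not None:
                trial_frames.append(session_frame(session, p.participant_id,
                                                  p.group))
        if p.tap_records:
            tap_frames.append(tap_frame(p.tap_records, p.participant_id))
        truth_rows.append({
            "participant_id": p.participant_id, "group": p.group,
            "latent": p.latent, "true_delay_m": p.true_delay_m,
            "true_aniso_m": p.true_aniso_m, "false_alarm": p.false_alarm,
            "true_mean_async": p.tapper.mean_async,
            "true_sd_async": p.tapper.sd_async,
            "true_mean_iti": p.tapper.continuation_mean_iti,
            "true_sd_iti": p.tapper.continuation_sd_iti,
            "true_drift": p.tapper.drift,
        })
    pd.concat(trial_frames, ignore_index=True).to_csv(out / "trials.csv",
                                                      index=False)
    pd.concat(tap_frames, ignore_index=True).to_csv(out / "taps.csv",
                                                    index=False)
    pd.DataFrame(truth_rows).to_csv(out / "cohort.csv", index=False)
    manifest = {
        "seed": cohort.seed,
        "groups": [{"label": g.label, "n": g.n, "latent_mean": g.latent_mean}
                   for g in cohort.groups],
        "config": {
            "latent_weight": cohort.config.latent_weight,
            "log_delay_base": cohort.config.log_delay_base,
            "log_aniso_base": cohort.config.log_aniso_base,
            "log_scale": cohort.config.log_scale,
            "fa_range": list(cohort.config.fa_range),
            "n_tap_blocks": cohort.config.n_tap_blocks,
            "observer_slope_k": cohort.config.observer_slope_k,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_trial_logs(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_tap_logs(path) -> pd.DataFrame:
    return pd.read_csv(path)


def blocks_from_frame(frame: pd.DataFrame) -> list[BlockResult]:
    """Rebuild experimental BlockResults from a trial-log frame (one
    participant x task; practice/training rows are ignored)."""
    blocks = []
    for b, sub in frame[frame.block_index >= 1].groupby("block_index"):
        sub = sub.sort_values("trial_index")
        trials = [Trial(index=int(r.trial_index), is_catch=bool(r.is_catch),
                        proposed_level=float(r.proposed_level_ms),
                        presented_level=float(r.presented_level_ms),
                        response=str(r.response),
                        ml_midpoint=float(r.ml_midpoint_ms),
                        ml_fa=float(r.ml_fa))
                  for r in sub.itertuples()]
        catch = [t for t in trials if t.is_catch]
        err = sum(t.response == "delayed" for t in catch)
        blocks.append(BlockResult(
            trials=trials, final_threshold=trials[-1].ml_midpoint,
            catch_error_rate=err / len(catch) if catch else 0.0))
    return blocks


def tap_records_from_frame(frame: pd.DataFrame,
                           ioi: float = 600.0) -> list[TapRecord]:
    """Rebuild TapRecords from a long-format tap log (one participant)."""
    records = []
    for _, sub in frame.groupby("block"):
        sync = sub[(sub.phase == "sync") & (sub.event_type == "tap")]
        clicks = sub[(sub.phase == "sync") & (sub.event_type == "click")]
        cont = sub[(sub.phase == "continuation") & (sub.event_type == "tap")]
        records.append(TapRecord(
            sync_taps=np.sort(sync.event_time_ms.to_numpy(dtype=float)),
            metronome_onsets=np.sort(clicks.event_time_ms.to_numpy(dtype=float)),
            continuation_taps=np.sort(cont.event_time_ms.to_numpy(dtype=float)),
            ioi=ioi))
    return records
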