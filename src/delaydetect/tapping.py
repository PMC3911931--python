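"""Synchronisation and continuation tapping statistics.

Synchronisation taps are paired to their nearest metronome onset within an
exclusive half-IOI window; asynchronies (tap minus onset, negative =
anticipation) feed both linear summaries (mean, SD) and circular ones: each
asynchrony becomes a phase on [0, 2pi), the mean resultant vector length
r measures phase locking, and Fisher's r-to-z transform (atanh) stabilises
it for parametric analysis.

Continuation tapping is summarised by the inter-tap-interval (ITI) series:
its mean and SD, the tempo drift (OLS slope of ITI on elapsed seconds), and
the residual coefficient of variation after detrending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from delaydetect.errors import InsufficientDataError, InvalidInputError

__all__ = [
    "TapRecord",
    "SyncStats",
    "ContinuationStats",
    "pair_taps",
    "circular_sync_stats",
    "continuation_stats",
    "participant_tapping_stats",
]

R_CLAMP = 1.0 - 1e-9


@dataclass(frozen=True)
class TapRecord:
    """One tapping block: sync taps, metronome onsets and continuation taps."""

    sync_taps: np.ndarray
    metronome_onsets: np.ndarray
    continuation_taps: np.ndarray
    ioi: float = 600.0

    def __post_init__(self) -> None:
        for name in ("sync_taps", "metronome_onsets", "continuation_taps"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise InvalidInputError(f"{name} must be strictly increasing")


@dataclass(frozen=True)
class SyncStats:
    """Linear and circular synchronisation summaries for one tap pool."""

    mean_async: float
    sd_async: float
    vector_length_r: float
    vector_z: float
    matched_tap_count: int
    clamped: bool = False   # r hit the atanh clamp (perfect synchrony)


@dataclass(frozen=True)
class ContinuationStats:
    """Continuation ITI summaries: raw moments, tempo drift, residual CV."""

    mean_iti: float
    sd_iti: float
    drift: float          # ms per second of elapsed continuation time
    residual_cv: float    # SD of detrended ITIs / mean ITI, percent
    n_itis: int


def pair_taps(taps, metronome_onsets, ioi: float = 600.0) -> np.ndarray:
    """Asynchronies of taps paired to their nearest onset.

    Each tap claims its nearest metronome onset; pairs farther than half an
    IOI (exclusive, so a tap exactly midway is dropped) are discarded, and
    when several taps claim one onset the whole onset is dropped.  Returns
    the asynchronies (tap - onset) of the surviving one-to-one pairs.
    """
    taps = np.asarray(taps, dtype=float)
    onsets = np.asarray(metronome_onsets, dtype=float)
    if taps.size == 0 or onsets.size == 0:
        raise InvalidInputError("taps and metronome onsets must be non-empty")
    idx = np.argmin(np.abs(taps[:, None] - onsets[None, :]), axis=1)
    asyncs = taps - onsets[idx]
    keep = np.abs(asyncs) < ioi / 2.0
    idx, asyncs = idx[keep], asyncs[keep]
    # drop onsets claimed by more than one tap
    uniq, counts = np.unique(idx, return_counts=True)
    contested = set(uniq[counts > 1])
    keep = np.array([i not in contested for i in idx], dtype=bool)
    asyncs = asyncs[keep]
    if asyncs.size == 0:
        raise InsufficientDataError("no tap/onset pairs formed")
    return asyncs


def circular_sync_stats(asynchronies, ioi: float = 600.0) -> SyncStats:
    """Linear and circular statistics of an asynchrony pool.

    Phases are ``2*pi*(asynchrony mod ioi)/ioi``; r is the mean resultant
    vector length and z its Fisher transform, with r clamped just below 1
    so that perfect synchrony stays finite (flagged via ``clamped``).
    """
    asyncs = np.asarray(asynchronies, dtype=float)
    if asyncs.size < 2:
        raise InsufficientDataError(
            f"need >= 2 asynchronies, got {asyncs.size}")
    phases = 2.0 * np.pi * np.mod(asyncs, ioi) / ioi
    r = float(np.abs(np.mean(np.exp(1j * phases))))
    clamped = r > R_CLAMP
    z = float(np.arctanh(min(r, R_CLAMP)))
    return SyncStats(mean_async=float(np.mean(asyncs)),
                     sd_async=float(np.std(asyncs, ddof=1)),
                     vector_length_r=r, vector_z=z,
                     matched_tap_count=int(asyncs.size), clamped=clamped)


def continuation_stats(continuation_taps) -> ContinuationStats:
    """ITI summaries of a continuation tap series.

    The drift is the OLS slope of ITI (ms) on the elapsed time (seconds
    since the first continuation tap) at which each interval starts; the
    residual CV is the SD of the detrended ITIs as a percentage of the mean
    ITI.
    """
    taps = np.asarray(continuation_taps, dtype=float)
    if taps.size < 3:
        raise InsufficientDataError(f"need >= 3 taps, got {taps.size}")
    if np.any(np.diff(taps) <= 0):
        raise InvalidInputError("continuation tap times must be increasing")
    itis = np.diff(taps)
    elapsed_sec = (taps[:-1] - taps[0]) / 1000.0
    slope, intercept = np.polyfit(elapsed_sec, itis, 1)
    residuals = itis - (intercept + slope * elapsed_sec)
    mean_iti = float(np.mean(itis))
    resid_sd = float(np.std(residuals, ddof=1)) if itis.size > 2 else 0.0
    return ContinuationStats(
        mean_iti=mean_iti,
        sd_iti=float(np.std(itis, ddof=1)),
        drift=float(slope),
        residual_cv=100.0 * resid_sd / mean_iti,
        n_itis=int(itis.size),
    )


def participant_tapping_stats(records) -> dict:
    """Per-participant tapping summary: block statistics averaged across
    blocks (each block is summarised first, then block values are averaged)."""
    sync_list, cont_list = [], []
    for rec in records:
        asyncs = pair_taps(rec.sync_taps, rec.metronome_onsets, rec.ioi)
        sync_list.append(circular_sync_stats(asyncs, rec.ioi))
        cont_list.append(continuation_stats(rec.continuation_taps))
    if not sync_list:
        raise InsufficientDataError("no tapping blocks")
    return {
        "mean_async": float(np.mean([s.mean_async for s in sync_list])),
        "sd_async": float(np.mean([s.sd_async for s in sync_list])),
        "vector_length_r": float(np.mean([s.vector_length_r for s in sync_list])),
        "vector_z": float(np.mean([s.vector_z for s in sync_list])),
        "mean_iti": float(np.mean([c.mean_iti for c in cont_list])),
        "sd_iti": float(np.mean([c.sd_iti for c in cont_list])),
        "drift": float(np.mean([c.drift for c in cont_list])),
        "residual_cv": float(np.mean([c.residual_cv for c in cont_list])),
        "n_blocks": len(sync_list),
    }
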