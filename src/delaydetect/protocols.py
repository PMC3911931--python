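"""Stimulus structures and session orchestration for the three tasks.

Sequences are symbolic onset timelines in ms; no audio is rendered.

* Anisochrony: five 100-ms tones at a 350-ms inter-onset interval.  A
  displacement ``d`` delays the fourth tone only — the third interval grows
  by ``d`` and the fourth shrinks by ``d`` — so the fifth tone is always on
  time at 4 x 350 = 1400 ms.
* Synchronisation-continuation: 4 lead-in snaps at 300 ms IOI, then 30
  metronome (woodblock) onsets at 600 ms IOI, then an 18000-ms silent
  continuation window (the equivalent of 30 more taps) closed by a gong.
* Adaptive sessions: 4 practice trials (two at zero, two at the task
  maximum, order randomised), a 10-trial training block starting at the
  maximum, then three 36-trial experimental blocks with 2+4 catch trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from delaydetect.config import TaskConfig
from delaydetect.errors import InvalidInputError
from delaydetect.mlp import (
    BlockResult,
    Trial,
    run_block,
    select_ml_curve,
    RESPONSE_DEVIANT,
)
from delaydetect.psychometric import CandidateGrid, build_candidate_grid

__all__ = [
    "AnisochronySequence",
    "SyncStimulusTimeline",
    "SessionResult",
    "build_anisochrony_sequence",
    "build_sync_stimulus",
    "run_session",
]

ANISO_BASE_IOI = 350.0
ANISO_TONE_DURATION = 100.0
SNAP_IOI = 300.0
N_SNAPS = 4
METRONOME_IOI = 600.0
N_METRONOME = 30
N_CONTINUATION = 30


@dataclass(frozen=True)
class AnisochronySequence:
    """Five tone onsets with the fourth displaced by ``d`` ms."""

    onsets: tuple[float, float, float, float, float]
    displacement_d: float
    tone_duration: float = ANISO_TONE_DURATION
    base_ioi: float = ANISO_BASE_IOI

    @property
    def intervals(self) -> tuple[float, ...]:
        return tuple(b - a for a, b in zip(self.onsets, self.onsets[1:]))


@dataclass(frozen=True)
class SyncStimulusTimeline:
    """Lead-in snaps, metronome onsets, silent continuation window, gong."""

    snap_onsets: tuple[float, ...]
    metronome_onsets: tuple[float, ...]
    continuation_window: float
    end_marker: float

    @property
    def ioi(self) -> float:
        return METRONOME_IOI


@dataclass
class SessionResult:
    """Practice log plus training and experimental block results."""

    task: str
    practice: list[Trial]
    training: BlockResult
    experimental: list[BlockResult]
    config: TaskConfig
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return (len(self.practice) + len(self.training.trials)
                + sum(len(b.trials) for b in self.experimental))


def build_anisochrony_sequence(d: float) -> AnisochronySequence:
    """Five-tone sequence with the fourth tone delayed by ``d`` ms.

    ``d = 0`` gives a perfectly isochronous sequence; ``d`` must stay below
    the 350-ms base IOI or the fourth interval would vanish.
    """
    if not np.isfinite(d) or d < 0 or d >= ANISO_BASE_IOI:
        raise InvalidInputError(
            f"displacement must satisfy 0 <= d < {ANISO_BASE_IOI}, got {d}")
    onsets = (0.0, ANISO_BASE_IOI, 2 * ANISO_BASE_IOI,
              3 * ANISO_BASE_IOI + d, 4 * ANISO_BASE_IOI)
    return AnisochronySequence(onsets=onsets, displacement_d=float(d))


def build_sync_stimulus() -> SyncStimulusTimeline:
    """Default synchronisation-continuation timeline."""
    snaps = tuple(i * SNAP_IOI for i in range(N_SNAPS))
    start = snaps[-1] + SNAP_IOI
    metronome = tuple(start + i * METRONOME_IOI for i in range(N_METRONOME))
    window = N_CONTINUATION * METRONOME_IOI
    gong = metronome[-1] + METRONOME_IOI + window
    return SyncStimulusTimeline(snap_onsets=snaps, metronome_onsets=metronome,
                                continuation_window=window, end_marker=gong)


def _practice_trials(task: TaskConfig, responder: Callable[[float], str],
                     rng: np.random.Generator) -> list[Trial]:
    levels = np.array([0.0, 0.0, task.max_level, task.max_level])
    rng.shuffle(levels)
    out = []
    for i, level in enumerate(levels):
        response = responder(float(level))
        out.append(Trial(index=i, is_catch=False, proposed_level=float(level),
                         presented_level=float(level), response=response,
                         ml_midpoint=task.range_ms[0], ml_fa=0.0))
    return out


def run_session(
    task: TaskConfig,
    responder: Callable[[float], str],
    seed: int | np.random.Generator | None = None,
) -> SessionResult:
    """Run one full adaptive session: practice, training, 3 experimental blocks.

    Practice trials give humans feedback; for the simulated-responder
    contract feedback is a no-op, so practice only logs the four responses.
    Training is a 10-trial adaptive block starting at the task maximum with
    no catch trials; each experimental block restarts the likelihood at the
    task maximum with the 2+4 catch schedule.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    grid = build_candidate_grid(task.midpoint_count, task.range_ms,
                                task.fa_rates, task.slope_k)
    practice = _practice_trials(task, responder, rng)
    training = run_block(grid, responder, task.training_length,
                         start_level=task.max_level, p_target=task.p_target,
                         rng=rng, catch_segments=None)
    experimental = []
    for _ in range(task.n_experimental_blocks):
        block = run_block(grid, responder, task.block_length,
                          start_level=task.max_level, p_target=task.p_target,
                          rng=rng, catch_segments=task.catch_segments)
        experimental.append(block)
    return SessionResult(task=task.name, practice=practice, training=training,
                         experimental=experimental, config=task,
                         seed=seed if isinstance(seed, int) else None)
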