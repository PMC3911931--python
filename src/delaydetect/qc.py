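"""Block-level quality control and threshold aggregation.

Two independent discard rules are applied to each experimental block:

* catch-error rule — discard when more than 30% of the block's catch
  trials (presented at zero) were answered "delayed";
* convergence rule — discard when the absolute OLS slope of the last 10
  per-trial threshold estimates exceeds the task cutoff (2 ms/trial for
  delay detection, 1.18 ms/trial for anisochrony).

A participant's threshold is the mean final estimate over blocks passing
both rules; participants with no surviving block are excluded.  Thresholds
are natural-log transformed for downstream parametric analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from delaydetect.errors import InvalidBlockError, InvalidInputError
from delaydetect.mlp import BlockResult, RESPONSE_DEVIANT

__all__ = [
    "ParticipantThreshold",
    "catch_error_filter",
    "convergence_filter",
    "aggregate_thresholds",
    "CATCH_ERROR_CUTOFF",
]

CATCH_ERROR_CUTOFF = 0.30
CONVERGENCE_WINDOW = 10


@dataclass(frozen=True)
class ParticipantThreshold:
    """Aggregated threshold for one participant on one task."""

    participant_id: str
    task: str
    retained_block_count: int
    threshold: float        # ms, mean over retained blocks
    log_threshold: float    # natural log


def catch_error_filter(block: BlockResult) -> bool:
    """Retain the block iff at most 30% of its catch trials drew a false
    alarm; blocks without catch trials pass vacuously."""
    catch = [t for t in block.trials if t.is_catch]
    if not catch:
        return True
    errors = sum(t.response == RESPONSE_DEVIANT for t in catch)
    return errors / len(catch) <= CATCH_ERROR_CUTOFF


def convergence_filter(block: BlockResult,
                       slope_cutoff: float) -> tuple[bool, float]:
    """OLS slope of the last 10 per-trial threshold estimates vs trial index.

    Returns ``(retained, slope)``; the block is retained iff |slope| does
    not exceed the cutoff.  The regression runs on the running ML midpoint
    estimates, the quantity whose convergence the rule is about.
    """
    if len(block.trials) < CONVERGENCE_WINDOW:
        raise InvalidBlockError(
            f"convergence filter needs >= {CONVERGENCE_WINDOW} trials, "
            f"got {len(block.trials)}")
    tail = block.ml_midpoints[-CONVERGENCE_WINDOW:]
    x = np.arange(CONVERGENCE_WINDOW, dtype=float)
    slope = float(np.polyfit(x, tail, 1)[0])
    # "exceeds the cutoff" is strict; guard the boundary against fp noise
    return abs(slope) <= slope_cutoff + 1e-9, slope


def apply_qc(block: BlockResult, slope_cutoff: float) -> BlockResult:
    """Annotate a block with both QC verdicts (in place) and return it."""
    retained_catch = catch_error_filter(block)
    retained_conv, slope = convergence_filter(block, slope_cutoff)
    block.convergence_slope = slope
    block.retained = retained_catch and retained_conv
    return block


def aggregate_thresholds(
    blocks,
    participant_id: str,
    task: str,
    slope_cutoff: float,
) -> ParticipantThreshold | None:
    """Mean threshold over blocks passing both filters.

    Returns ``None`` when no block survives (the participant is excluded
    from downstream tables).
    """
    retained = []
    for block in blocks:
        apply_qc(block, slope_cutoff)
        if block.retained:
            retained.append(block.final_threshold)
    if not retained:
        return None
    threshold = float(np.mean(retained))
    if threshold <= 0:
        raise InvalidInputError(
            f"non-positive aggregated threshold {threshold} cannot be "
            "log-transformed")
    return ParticipantThreshold(
        participant_id=participant_id, task=task,
        retained_block_count=len(retained),
        threshold=threshold, log_threshold=math.log(threshold))
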