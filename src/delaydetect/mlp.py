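"""Adaptive Maximum Likelihood Procedure (MLP).

After every response the engine scores each candidate psychometric curve by
the log-likelihood of all responses so far (catch trials included, at their
presented level of 0 ms), takes the maximally likely curve, and inverts it
at the tracking probability ``p_target`` to place the next stimulus.  The
block's threshold estimate is the midpoint of the final maximum-likelihood
curve.

Catch trials are presented at 0 ms regardless of the adaptive suggestion;
their responses enter the likelihood, which is what lets the false-alarm
dimension of the candidate grid absorb response bias.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from delaydetect.errors import (
    InvalidConfigError,
    InvalidInputError,
    InvalidTargetError,
)
from delaydetect.psychometric import CandidateGrid, PsychometricCurve

__all__ = [
    "Trial",
    "BlockResult",
    "log_likelihood",
    "select_ml_curve",
    "next_stimulus",
    "schedule_catch_trials",
    "run_block",
    "DEFAULT_CATCH_SEGMENTS",
]

_P_CLAMP = 1e-12

#: experimental-block catch layout: 2 catch trials in the first 12 positions,
#: 4 in the following 24
DEFAULT_CATCH_SEGMENTS: tuple[tuple[int, int], ...] = ((12, 2), (24, 4))

RESPONSE_DEVIANT = "delayed"
RESPONSE_STANDARD = "immediate"


@dataclass(frozen=True)
class Trial:
    """One presentation and its post-trial maximum-likelihood state."""

    index: int
    is_catch: bool
    proposed_level: float      # what the adaptive rule suggested, ms
    presented_level: float     # 0 on catch trials
    response: str              # "delayed" | "immediate"
    ml_midpoint: float         # midpoint of the ML curve after this trial, ms
    ml_fa: float               # false-alarm rate of the ML curve

    def __post_init__(self) -> None:
        if self.is_catch and self.presented_level != 0.0:
            raise InvalidInputError("catch trials are presented at 0 ms")
        if self.response not in (RESPONSE_DEVIANT, RESPONSE_STANDARD):
            raise InvalidInputError(f"unknown response {self.response!r}")


@dataclass
class BlockResult:
    """An ordered trial log with its final estimate and QC annotations."""

    trials: list[Trial]
    final_threshold: float
    catch_error_rate: float
    convergence_slope: float | None = None
    retained: bool | None = None
    aborted: bool = False

    @property
    def ml_midpoints(self) -> np.ndarray:
        return np.array([t.ml_midpoint for t in self.trials])


def _response_is_deviant(response: str) -> bool:
    if response not in (RESPONSE_DEVIANT, RESPONSE_STANDARD):
        raise InvalidInputError(f"unknown response {response!r}")
    return response == RESPONSE_DEVIANT


def log_likelihood(curve: PsychometricCurve, trials: Sequence[Trial]) -> float:
    """Log-likelihood of a trial log under one candidate curve.

    Sums log p for "delayed" responses and log(1-p) for "immediate" ones,
    with p evaluated at each trial's *presented* level.  Probabilities are
    clamped away from 0 and 1 before the log; a clamp that meets the
    contradicting response raises a warning rather than -inf.
    """
    total = 0.0
    for t in trials:
        p = curve.probability(t.presented_level)
        deviant = _response_is_deviant(t.response)
        if (p <= _P_CLAMP and deviant) or (p >= 1.0 - _P_CLAMP and not deviant):
            warnings.warn(
                "response probability clamped against the observed response; "
                "likelihood is a floor value", RuntimeWarning, stacklevel=2)
        p = min(max(p, _P_CLAMP), 1.0 - _P_CLAMP)
        total += math.log(p) if deviant else math.log1p(-p)
    return total


def _grid_log_likelihood_update(grid: CandidateGrid, loglik: np.ndarray,
                                level: float, response: str) -> None:
    """Add one trial's contribution to the per-curve accumulator in place."""
    p = np.clip(grid.probabilities(level), _P_CLAMP, 1.0 - _P_CLAMP)
    if _response_is_deviant(response):
        loglik += np.log(p)
    else:
        loglik += np.log1p(-p)


def _argmax_tiebreak(grid: CandidateGrid, loglik: np.ndarray) -> int:
    # grid is midpoint-major ascending, so the first maximum realises the
    # smallest-m-then-smallest-a tie-break
    return int(np.argmax(loglik > np.max(loglik) - 1e-12))


def select_ml_curve(grid: CandidateGrid,
                    trials: Sequence[Trial]) -> PsychometricCurve:
    """Candidate curve that makes the responses maximally likely.

    Ties are broken toward the smallest midpoint, then the smallest
    false-alarm rate; with no trials every curve ties and the first grid
    curve is returned.
    """
    if len(grid) == 0:
        raise InvalidConfigError("empty candidate grid")
    loglik = np.zeros(len(grid))
    for t in trials:
        _grid_log_likelihood_update(grid, loglik, t.presented_level, t.response)
    return grid.curve(_argmax_tiebreak(grid, loglik))


def next_stimulus(curve: PsychometricCurve, p_target: float,
                  stimulus_range: tuple[float, float]) -> float:
    """Stimulus level at which ``curve`` predicts ``p_target``, clamped to
    the task range.

    Closed-form inverse of the logistic model:
    ``x = m + (1/k) * ln((p_target - a) / (1 - p_target))``.
    """
    a = curve.false_alarm_a
    if not (a < p_target < 1.0):
        raise InvalidTargetError(
            f"p_target must lie in (a, 1) = ({a}, 1), got {p_target}")
    x = curve.midpoint_m + math.log((p_target - a) / (1.0 - p_target)) / curve.slope_k
    return float(min(max(x, stimulus_range[0]), stimulus_range[1]))


def schedule_catch_trials(
    block_length: int,
    rng: np.random.Generator | int,
    segments: Sequence[tuple[int, int]] = DEFAULT_CATCH_SEGMENTS,
) -> np.ndarray:
    """Boolean catch mask for one block.

    ``segments`` is a sequence of ``(length, n_catch)`` pairs partitioning
    the block; catch positions are uniform within each segment.  The
    experimental default places 2 catch trials in the first 12 positions
    and 4 in the next 24.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    seg_total = sum(length for length, _ in segments)
    if seg_total != block_length:
        raise InvalidConfigError(
            f"segments cover {seg_total} trials but block_length={block_length}")
    for length, n_catch in segments:
        if not 0 <= n_catch <= length:
            raise InvalidConfigError(
                f"cannot place {n_catch} catch trials in a {length}-trial segment")
    mask = np.zeros(block_length, dtype=bool)
    offset = 0
    for length, n_catch in segments:
        pos = rng.choice(length, size=n_catch, replace=False)
        mask[offset + pos] = True
        offset += length
    return mask


def run_block(
    grid: CandidateGrid,
    responder: Callable[[float], str],
    block_length: int,
    start_level: float,
    p_target: float = 0.707,
    rng: np.random.Generator | int | None = None,
    catch_segments: Sequence[tuple[int, int]] | None = None,
) -> BlockResult:
    """Run one adaptive block against a responder callable.

    The first trial is presented at ``start_level``; every subsequent
    non-catch trial at the inverse of the current maximum-likelihood curve
    at ``p_target``.  Catch trials (scheduled when ``catch_segments`` is
    given) are presented at 0 ms but their responses still enter the
    likelihood.  The per-curve log-likelihood accumulator starts from zero:
    blocks are independent.

    If the responder raises, the partial log is preserved in the returned
    result with ``aborted=True``.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if catch_segments is not None:
        catch_mask = schedule_catch_trials(block_length, rng, catch_segments)
    else:
        catch_mask = np.zeros(block_length, dtype=bool)

    stimulus_range = grid.midpoint_range
    loglik = np.zeros(len(grid))
    trials: list[Trial] = []
    aborted = False
    proposed = float(start_level)

    for i in range(block_length):
        is_catch = bool(catch_mask[i])
        presented = 0.0 if is_catch else proposed
        try:
            response = responder(presented)
        except Exception:
            aborted = True
            break
        _grid_log_likelihood_update(grid, loglik, presented, response)
        best = _argmax_tiebreak(grid, loglik)
        ml_m = float(grid.midpoints[best])
        ml_a = float(grid.fas[best])
        trials.append(Trial(index=i, is_catch=is_catch,
                            proposed_level=proposed, presented_level=presented,
                            response=response, ml_midpoint=ml_m, ml_fa=ml_a))
        proposed = next_stimulus(grid.curve(best), p_target, stimulus_range)

    n_catch = sum(t.is_catch for t in trials)
    n_catch_err = sum(t.is_catch and t.response == RESPONSE_DEVIANT
                      for t in trials)
    catch_error_rate = n_catch_err / n_catch if n_catch else 0.0
    final = trials[-1].ml_midpoint if trials else float("nan")
    return BlockResult(trials=trials, final_threshold=final,
                       catch_error_rate=catch_error_rate, aborted=aborted)
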