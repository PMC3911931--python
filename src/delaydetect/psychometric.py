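"""Logistic psychometric response model and candidate-curve grids.

The probability that an observer reports a stimulus of level ``x`` (a
keystroke-sound delay or an anisochrony displacement, in ms) as deviant is
modelled as

    p(x) = a + (1 - a) / (1 + exp(-k * (x - m)))

where ``a`` is the false-alarm rate (the lower asymptote: the probability
of reporting "delayed" at zero delay), ``k`` the slope (per ms) and ``m``
the midpoint (ms), which serves as the threshold parameter.  The adaptive
procedure maintains a grid of such curves — midpoints linearly spaced over
the task's stimulus range crossed with a small set of false-alarm rates —
and scores each by the likelihood of the responses observed so far.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from delaydetect.errors import InvalidConfigError, InvalidInputError

__all__ = [
    "PsychometricCurve",
    "CandidateGrid",
    "evaluate_probability",
    "build_candidate_grid",
]


@dataclass(frozen=True)
class PsychometricCurve:
    """One candidate hypothesis: midpoint ``m`` (ms), slope ``k`` (1/ms),
    false-alarm rate ``a`` in [0, 1)."""

    midpoint_m: float
    slope_k: float
    false_alarm_a: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("midpoint_m", self.midpoint_m),
                        ("slope_k", self.slope_k),
                        ("false_alarm_a", self.false_alarm_a)):
            if not math.isfinite(v):
                raise InvalidInputError(f"{name} must be finite, got {v!r}")
        if self.slope_k <= 0:
            raise InvalidInputError(f"slope_k must be > 0, got {self.slope_k}")
        if not 0.0 <= self.false_alarm_a < 1.0:
            raise InvalidInputError(
                f"false_alarm_a must lie in [0, 1), got {self.false_alarm_a}")

    def probability(self, x: float) -> float:
        return evaluate_probability(self, x)


@dataclass(frozen=True)
class CandidateGrid:
    """Ordered collection of candidate curves sharing one slope.

    Curves are ordered midpoint-major (ascending midpoint, then ascending
    false-alarm rate), which makes first-occurrence argmax implement the
    smallest-m-then-smallest-a tie-break used by the adaptive engine.
    """

    midpoint_count: int
    midpoint_range: tuple[float, float]
    fa_rates: tuple[float, ...]
    slope_k: float
    # flat parameter arrays, midpoint-major
    midpoints: np.ndarray = field(repr=False)
    fas: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.midpoints.size

    @property
    def curves(self) -> list[PsychometricCurve]:
        return [PsychometricCurve(m, self.slope_k, a)
                for m, a in zip(self.midpoints, self.fas)]

    def curve(self, index: int) -> PsychometricCurve:
        return PsychometricCurve(float(self.midpoints[index]), self.slope_k,
                                 float(self.fas[index]))

    def probabilities(self, x: float) -> np.ndarray:
        """Vector of p(x) over all candidate curves (numerically stable)."""
        if not math.isfinite(x):
            raise InvalidInputError(f"stimulus level must be finite, got {x!r}")
        core = expit(self.slope_k * (x - self.midpoints))
        return self.fas + (1.0 - self.fas) * core


def evaluate_probability(curve: PsychometricCurve, x: float) -> float:
    """Probability of a "deviant"/"delayed" response at stimulus level ``x`` ms.

    Strictly inside (a, 1) for finite x and monotone non-decreasing in x.
    """
    if not isinstance(x, (int, float)) or not math.isfinite(x):
        raise InvalidInputError(f"stimulus level must be finite, got {x!r}")
    a = curve.false_alarm_a
    return a + (1.0 - a) * float(expit(curve.slope_k * (x - curve.midpoint_m)))


def build_candidate_grid(
    midpoint_count: int,
    midpoint_range: tuple[float, float],
    fa_rates,
    slope_k: float,
) -> CandidateGrid:
    """Build the candidate grid: ``midpoint_count`` midpoints linearly spaced
    over ``midpoint_range`` (endpoints included) crossed with ``fa_rates``.

    The delay-detection task uses 600 midpoints over 0-600 ms and five
    false-alarm rates (0, .1, .2, .3, .4), i.e. 3000 candidates; the
    anisochrony task uses 200 midpoints over 0-200 ms, i.e. 1000.
    """
    fa_rates = tuple(float(a) for a in fa_rates)
    if not fa_rates:
        raise InvalidConfigError("fa_rates must be non-empty")
    if midpoint_count < 1:
        raise InvalidConfigError(f"midpoint_count must be >= 1, got {midpoint_count}")
    lo, hi = float(midpoint_range[0]), float(midpoint_range[1])
    if not (lo < hi):
        raise InvalidConfigError(f"midpoint_range must satisfy lo < hi, got {lo, hi}")
    if any(not 0.0 <= a < 1.0 for a in fa_rates):
        raise InvalidConfigError(f"fa_rates must lie in [0, 1): {fa_rates}")
    if slope_k <= 0 or not math.isfinite(slope_k):
        raise InvalidConfigError(f"slope_k must be finite and > 0, got {slope_k}")

    mids = np.linspace(lo, hi, midpoint_count) if midpoint_count > 1 \
        else np.array([lo])
    fas = np.asarray(sorted(fa_rates), dtype=float)
    # midpoint-major flattening
    midpoints = np.repeat(mids, fas.size)
    fa_flat = np.tile(fas, mids.size)
    return CandidateGrid(
        midpoint_count=midpoint_count,
        midpoint_range=(lo, hi),
        fa_rates=tuple(fas),
        slope_k=float(slope_k),
        midpoints=midpoints,
        fas=fa_flat,
    )
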