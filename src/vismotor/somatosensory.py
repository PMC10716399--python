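"""Tactile acuity (grating orientation task) and mechanical detection
threshold estimation.

GOT: plastic gratings of descending groove spacing (3.5 down to 0.5 mm) are
presented 10 times each in random transversal/longitudinal orientation
(chance level 0.5) until accuracy drops below the pass criterion (8/10).
The acuity threshold ``g75`` is the groove spacing at which the subject
would have scored 75% correct, obtained by linear interpolation between the
adjacent spacings bracketing 75% accuracy.

MDT: von-Frey filaments on a geometric force ladder (0.25-8 mN, factor 2)
presented by the method of limits — alternately descending until the
stimulus is missed and ascending until it is noticed again, two
determinations of 10 stimuli each.  The threshold surrogate is the mean of
the turning-point forces, with their standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataIntegrityError, MissingDataError, UndefinedRatioError

#: pass criterion: at least 8 of 10 correct (the parenthetical 8/10 rule)
DEFAULT_PASS_FRACTION = 0.8
TARGET_ACCURACY = 0.75

MDT_FORCE_LADDER = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)  # mN, factor 2


@dataclass(frozen=True)
class GOTBlock:
    """Ten same-spacing grating presentations."""

    spacing_mm: float
    n_trials: int
    n_correct: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_correct <= self.n_trials):
            raise DataIntegrityError(
                f"n_correct {self.n_correct} outside [0, {self.n_trials}]"
            )

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_trials


@dataclass(frozen=True)
class ThresholdEstimate:
    """A threshold with optional SE and a censoring flag.

    ``censored`` is ``None`` for a proper interior estimate, ``"floor"``
    when performance never failed (true threshold below the tested range)
    and ``"ceiling"`` when it failed immediately (threshold above range).
    """

    value: float
    se: float | None = None
    censored: str | None = None


def got_termination(
    blocks: Sequence[GOTBlock], pass_fraction: float = DEFAULT_PASS_FRACTION
) -> tuple[list[GOTBlock], bool]:
    """Truncate a descending-spacing block list at the stop rule.

    Returns the blocks up to and including the first one whose accuracy
    falls below ``pass_fraction`` plus a flag that is True when no block
    failed (floor not reached).
    """
    blocks = list(blocks)
    if not blocks:
        raise MissingDataError("got_termination requires at least one block")
    spacings = [b.spacing_mm for b in blocks]
    if any(narrower >= wider for narrower, wider in zip(spacings[1:], spacings)):
        raise DataIntegrityError("GOT blocks must be ordered by descending spacing")
    kept: list[GOTBlock] = []
    for b in blocks:
        kept.append(b)
        if b.accuracy < pass_fraction:
            return kept, False
    return kept, True


def g75(blocks: Sequence[GOTBlock]) -> ThresholdEstimate:
    """Interpolated groove spacing at 75% accuracy.

    Uses the bracketing pair adjacent to the termination point: the last
    (widest-spacing) block at or above 75% accuracy (``g_low``, easier) and
    the following narrower block below 75% (``g_high``):

        g75 = g_low + ((0.75 - p_low) / (p_high - p_low)) * (g_high - g_low)

    Without a bracketing pair the estimate is censored at the boundary of
    the tested ladder.
    """
    blocks = list(blocks)
    if not blocks:
        raise MissingDataError("g75 requires GOT blocks")
    acc = [b.accuracy for b in blocks]
    if acc[0] < TARGET_ACCURACY:
        # failed at the widest spacing: threshold above the tested range
        return ThresholdEstimate(blocks[0].spacing_mm, censored="ceiling")
    # last index at/above criterion that is directly followed by a failure
    for i in range(len(blocks) - 1, 0, -1):
        if acc[i] < TARGET_ACCURACY and acc[i - 1] >= TARGET_ACCURACY:
            low, high = blocks[i - 1], blocks[i]
            p_low, p_high = low.accuracy, high.accuracy
            if p_low == TARGET_ACCURACY:
                return ThresholdEstimate(low.spacing_mm)
            value = low.spacing_mm + (
                (TARGET_ACCURACY - p_low) / (p_high - p_low)
            ) * (high.spacing_mm - low.spacing_mm)
            return ThresholdEstimate(value)
    # every block passed: threshold below the narrowest tested spacing
    return ThresholdEstimate(blocks[-1].spacing_mm, censored="floor")


@dataclass(frozen=True)
class MDTSeries:
    """Method-of-limits stimulus/response sequence for one subject/phase.

    ``runs`` concatenates the determinations; each item is (force_mN,
    detected).  ``determination`` indexes which 10-stimulus determination a
    trial belongs to (turning points are extracted within determinations).
    """

    runs: tuple[tuple[float, bool], ...]
    determination: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.runs) != len(self.determination):
            raise DataIntegrityError("runs and determination lengths differ")


def turning_points(series: MDTSeries) -> list[float]:
    """Forces at detection<->non-detection reversals between consecutive
    stimuli, extracted within each determination."""
    points: list[float] = []
    for det in sorted(set(series.determination)):
        seq = [r for r, d in zip(series.runs, series.determination) if d == det]
        for (f_prev, d_prev), (f_cur, d_cur) in zip(seq, seq[1:]):
            if d_cur != d_prev:
                points.append(f_cur)
    return points


def mdt_threshold(
    series: MDTSeries, *, geometric: bool = False
) -> ThresholdEstimate:
    """Mechanical detection threshold: mean (default arithmetic) of the
    turning-point forces with their standard error.

    A series without any reversal is censored at the ladder boundary: all
    detected -> floor (0.25 mN); none detected -> ceiling (8 mN).
    """
    if not series.runs:
        raise MissingDataError("mdt_threshold requires stimuli")
    points = turning_points(series)
    if not points:
        detected_all = all(d for _, d in series.runs)
        bound = MDT_FORCE_LADDER[0] if detected_all else MDT_FORCE_LADDER[-1]
        return ThresholdEstimate(
            bound, censored="floor" if detected_all else "ceiling"
        )
    arr = np.asarray(points, dtype=float)
    if geometric:
        mean = float(np.exp(np.mean(np.log(arr))))
    else:
        mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return ThresholdEstimate(mean, se=se)


def relative_change(pre: float, post: float) -> float:
    """Post/pre ratio of a threshold (or any positive measure)."""
    if pre <= 0:
        raise UndefinedRatioError(f"pre value must be positive, got {pre}")
    return post / pre
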