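"""Touch-typing learning scores.

Three bespoke per-subject scores summarise motor-skill acquisition over a
five-day typing course with two daily 45-min sessions of twelve 3-min
lessons:

* ``Gain_L3`` — between-day learning: mean correct characters in the marker
  lesson (L3) on day X divided by the day-1 mean.  Day 1 pools all eight L3
  occurrences (four per session); ``Gain_L3`` of day 1 versus day 1 is 1 by
  construction.
* ``DI`` (daily improvement) — within-day learning: total correct characters
  across all lessons of the afternoon session divided by the morning total.
* ``MLE`` (motor learning efficiency) — the mean of the ten Gain_L3 and DI
  values (five days each); *not* maximum-likelihood estimation.

A lesson's correct count is ``entered - errors``.  All three scores are
ratios, hence invariant under uniform scaling of counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataIntegrityError,
    MissingDataError,
    UndefinedBaselineError,
)

MARKER_LESSON = "L3"

#: days of the training course
DAYS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class LessonRecord:
    """One 3-min typing lesson attempt."""

    subject_id: str
    group: str  # "TV" or "NOTV"
    day: int  # 1..5
    session: int  # 1 (morning) or 2 (afternoon)
    lesson_id: str  # marker lesson flagged as "L3"
    entered: int
    errors: int
    duration_min: float = 3.0

    def __post_init__(self) -> None:
        if not (0 <= self.errors <= self.entered):
            raise DataIntegrityError(
                f"errors ({self.errors}) must lie in [0, entered={self.entered}]"
            )
        if self.day not in DAYS:
            raise DataIntegrityError(f"day must be in 1..5, got {self.day}")
        if self.duration_min <= 0:
            raise DataIntegrityError("duration must be positive")

    @property
    def is_marker(self) -> bool:
        return self.lesson_id == MARKER_LESSON


def correct_count(record: LessonRecord) -> int:
    """Correctly entered characters of one lesson: ``entered - errors``."""
    if record.errors > record.entered:
        raise DataIntegrityError("errors exceed entered characters")
    return record.entered - record.errors


def _mean_correct(records: Sequence[LessonRecord]) -> float:
    return float(np.mean([correct_count(r) for r in records]))


def gain_l3(
    day_x_marker: Sequence[LessonRecord], day_1_marker: Sequence[LessonRecord]
) -> float:
    """Between-day gain: mean marker-lesson correct count, day X over day 1.

    Both collections must consist of marker-lesson (L3) records only; the
    day-1 collection pools all of that day's occurrences across both
    sessions.  Identical collections give exactly 1.
    """
    if not day_x_marker or not day_1_marker:
        raise MissingDataError("gain_l3 requires non-empty marker-lesson records")
    for rec in (*day_x_marker, *day_1_marker):
        if not rec.is_marker:
            raise DataIntegrityError(
                f"gain_l3 expects only marker-lesson records, got {rec.lesson_id}"
            )
    baseline = _mean_correct(day_1_marker)
    if baseline == 0:
        raise UndefinedBaselineError("day-1 mean correct count is zero")
    return _mean_correct(day_x_marker) / baseline


def daily_improvement(day_records: Sequence[LessonRecord]) -> float:
    """Within-day improvement: session-2 total correct over session-1 total.

    Uses *all* lessons of the day, not only the marker lesson.  Returns NaN
    when one of the two sessions is absent (missingness is tolerated and
    propagated as NaN rather than raised).
    """
    if not day_records:
        raise MissingDataError("daily_improvement requires records")
    days = {r.day for r in day_records}
    if len(days) != 1:
        raise DataIntegrityError(f"records span multiple days: {sorted(days)}")
    s1 = [r for r in day_records if r.session == 1]
    s2 = [r for r in day_records if r.session == 2]
    if not s1 or not s2:
        return math.nan
    total1 = sum(correct_count(r) for r in s1)
    total2 = sum(correct_count(r) for r in s2)
    if total1 == 0:
        raise UndefinedBaselineError("session-1 total correct count is zero")
    return total2 / total1


def motor_learning_efficiency(
    gains: Sequence[float], dis: Sequence[float]
) -> float:
    """Composite learning score: mean of the five gains and five DIs.

    Missing (NaN) components are dropped and the divisor reduced
    accordingly; with all ten values present this is ``(sum gains + sum
    dis) / 10``.
    """
    values = [v for v in (*gains, *dis) if not math.isnan(v)]
    if not values:
        raise MissingDataError("all Gain_L3 / DI components are missing")
    return float(np.mean(values))


def dictation_ccpm(correct_chars: int, minutes: float) -> float:
    """Correct characters per minute in a dictation block."""
    if minutes <= 0:
        raise ConfigurationError(f"minutes must be positive, got {minutes}")
    return correct_chars / minutes


# ---------------------------------------------------------------------------
# table-level scoring (typing.csv -> scores.csv)
# ---------------------------------------------------------------------------

TYPING_COLUMNS = [
    "subject_id",
    "group",
    "day",
    "session",
    "lesson_id",
    "entered",
    "errors",
    "duration_min",
]


def records_from_frame(df: pd.DataFrame) -> list[LessonRecord]:
    """Convert a typing table into validated :class:`LessonRecord` objects."""
    return [
        LessonRecord(
            subject_id=str(row.subject_id),
            group=str(row.group),
            day=int(row.day),
            session=int(row.session),
            lesson_id=str(row.lesson_id),
            entered=int(row.entered),
            errors=int(row.errors),
            duration_min=float(row.duration_min),
        )
        for row in df.itertuples(index=False)
    ]


def subject_scores(records: Iterable[LessonRecord]) -> dict:
    """All learning scores for one subject's lesson records."""
    records = list(records)
    if not records:
        raise MissingDataError("no lesson records for subject")
    subject = records[0].subject_id
    group = records[0].group
    markers = {d: [r for r in records if r.is_marker and r.day == d] for d in DAYS}
    if not markers[1]:
        raise MissingDataError(f"subject {subject}: no day-1 marker lessons")
    gains = []
    for d in DAYS:
        gains.append(gain_l3(markers[d], markers[1]) if markers[d] else math.nan)
    dis = []
    for d in DAYS:
        day_recs = [r for r in records if r.day == d]
        dis.append(daily_improvement(day_recs) if day_recs else math.nan)
    mle = motor_learning_efficiency(gains, dis)
    complete = not any(math.isnan(v) for v in (*gains, *dis))
    out = {"subject_id": subject, "group": group}
    out.update({f"gain_l3_d{d}": g for d, g in zip(DAYS, gains)})
    out.update({f"di_d{d}": v for d, v in zip(DAYS, dis)})
    out["mle"] = mle
    out["mle_complete"] = complete
    return out


def score_table(typing: pd.DataFrame) -> pd.DataFrame:
    """Per-subject score table (one row per subject) from a typing table."""
    rows = []
    for _, sub_df in typing.groupby("subject_id", sort=True):
        rows.append(subject_scores(records_from_frame(sub_df)))
    return pd.DataFrame(rows)
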