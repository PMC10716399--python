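import numpy as np
import pytest

from vismotor.typing_scores import LessonRecord


def marker_records(correct_counts, day, session=1, subject="S001", group="TV"):
    """Marker-lesson records with the given correct counts (errors = 0)."""
    return [
        LessonRecord(
            subject_id=subject, group=group, day=day, session=session,
            lesson_id="L3", entered=int(c), errors=0,
        )
        for c in correct_counts
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
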