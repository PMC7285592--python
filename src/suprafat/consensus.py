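"""Goutallier grading by multiple raters and the consensus (majority) grade.

The Goutallier scale grades fatty infiltration of a rotator-cuff muscle
from 0 (no fat) through 1 (fatty streaks), 2 (fat clearly present but less
than muscle), 3 (as much fat as muscle) to 4 (more fat than muscle).  With
several independent raters the consensus grade is the rater mean rounded
to the nearest integer; no tie-breaker re-read is performed.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

from .errors import InputError

GRADES = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class GoutallierRating:
    subject_id: str
    rater_id: str
    grade: int

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise InputError(f"grade must be in {GRADES}, got {self.grade}")


@dataclass(frozen=True)
class ConsensusGrade:
    subject_id: str
    mean_grade: float
    final_grade: int
    n_raters: int


def consensus_grade(ratings: list[GoutallierRating]) -> ConsensusGrade:
    """Average the raters' grades and round half-up to the final grade.

    With three raters the mean is a multiple of 1/3 and the .5 tie never
    occurs; half-up is the documented rule for even rater counts.
    """
    if len(ratings) < 2:
        raise InputError("consensus requires at least 2 ratings")
    subjects = {r.subject_id for r in ratings}
    if len(subjects) != 1:
        raise InputError(f"ratings mix subjects: {sorted(subjects)}")
    mean = sum(r.grade for r in ratings) / len(ratings)
    final = int(min(max(math.floor(mean + 0.5), GRADES[0]), GRADES[-1]))
    return ConsensusGrade(
        subject_id=ratings[0].subject_id,
        mean_grade=mean,
        final_grade=final,
        n_raters=len(ratings),
    )


def consensus_grades(ratings: list[GoutallierRating]) -> list[ConsensusGrade]:
    """Per-subject consensus over a flat list of ratings, ordered by first appearance."""
    by_subject: dict[str, list[GoutallierRating]] = defaultdict(list)
    for r in ratings:
        by_subject[r.subject_id].append(r)
    return [consensus_grade(rs) for rs in by_subject.values()]


def group_by_grade(
    consensus: list[ConsensusGrade],
    measurements: dict[str, float],
) -> dict[int, list[float]]:
    """Partition per-subject measurements into final-grade groups.

    The partition is exhaustive and disjoint over the measured subjects;
    a measurement without a consensus grade is an input error.
    """
    grade_of = {c.subject_id: c.final_grade for c in consensus}
    groups: dict[int, list[float]] = {}
    for subject, value in measurements.items():
        if subject not in grade_of:
            raise InputError(f"no consensus grade for subject {subject!r}")
        groups.setdefault(grade_of[subject], []).append(float(value))
    return groups
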