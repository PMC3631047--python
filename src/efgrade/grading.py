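"""Quadrant-based ordinal grading of epidural fibrosis and its aggregation.

The scoring model works on axial slices of the postoperative lumbar spinal
canal.  Each slice is divided into four quadrants (A/B = right/left anterior,
C/D = right/left posterior epidural space) and each quadrant receives an
ordinal grade 0-4 according to the fraction of the quadrant occupied by scar
tissue:

====== =====================
grade  quadrant affected
====== =====================
0      none / trace
1      1-25 %
2      26-50 %
3      51-75 %
4      76-100 %
====== =====================

Because a quarter of a quadrant is a sixteenth of the slice, the sum of the
four grades (0-16) counts sixteenths of the slice affected; dividing by 16
and multiplying by 100 yields the per-slice fibrosis percentage.  Averaging
the per-slice percentages over the ``n`` slices covering an operative level
yields the segment percentage -- the "total amount" of fibrosis used to
compare treatment groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "QUADRANTS",
    "QuadrantGrade",
    "SliceAssessment",
    "SegmentAssessment",
    "grade_from_fraction",
    "slice_sum_score",
    "slice_percent",
    "segment_percent",
]

#: Quadrant labels in canonical order: right/left anterior, right/left posterior.
QUADRANTS: tuple[str, ...] = ("A", "B", "C", "D")

#: Default allowance for "trace" fibrosis, as a fraction of the quadrant.
DEFAULT_TRACE_THRESHOLD = 0.005


class GradingError(ValueError):
    """Invalid grade, quadrant label, or aggregation input."""


@dataclass(frozen=True)
class QuadrantGrade:
    """Ordinal 0-4 fibrosis grade for one quadrant of one axial slice."""

    quadrant: str
    grade: int

    def __post_init__(self) -> None:
        if self.quadrant not in QUADRANTS:
            raise GradingError(
                f"quadrant must be one of {QUADRANTS}, got {self.quadrant!r}"
            )
        if not isinstance(self.grade, (int,)) or isinstance(self.grade, bool):
            raise GradingError(f"grade must be an integer, got {self.grade!r}")
        if not 0 <= self.grade <= 4:
            raise GradingError(f"grade must be in 0..4, got {self.grade}")


def _as_quadrant_grades(
    grades: Sequence[QuadrantGrade] | Mapping[str, int] | Sequence[int],
) -> tuple[QuadrantGrade, ...]:
    """Normalize grade input to one :class:`QuadrantGrade` per quadrant A-D.

    Accepts four :class:`QuadrantGrade`, a mapping ``{label: grade}``, or a
    plain sequence of four integers taken in A, B, C, D order.
    """
    if isinstance(grades, Mapping):
        items = [QuadrantGrade(q, int(g)) for q, g in grades.items()]
    else:
        seq = list(grades)
        if seq and all(isinstance(g, QuadrantGrade) for g in seq):
            items = list(seq)  # type: ignore[arg-type]
        else:
            if len(seq) != 4:
                raise GradingError(
                    f"expected 4 quadrant grades, got {len(seq)}"
                )
            items = [QuadrantGrade(q, int(g)) for q, g in zip(QUADRANTS, seq)]
    labels = [g.quadrant for g in items]
    if sorted(labels) != sorted(QUADRANTS):
        raise GradingError(
            f"need exactly one grade per quadrant {QUADRANTS}, got labels {labels}"
        )
    items.sort(key=lambda g: g.quadrant)
    return tuple(items)


@dataclass(frozen=True)
class SliceAssessment:
    """Four quadrant grades of one slice plus the derived slice-level scores.

    ``slice_sum`` is the sum of the four grades (0-16), counting affected
    sixteenths of the slice; ``slice_percent`` is ``slice_sum / 16 * 100``.
    """

    grades: tuple[QuadrantGrade, ...]
    slice_sum: int = field(init=False)
    slice_percent: float = field(init=False)

    def __post_init__(self) -> None:
        grades = _as_quadrant_grades(self.grades)
        object.__setattr__(self, "grades", grades)
        s = sum(g.grade for g in grades)
        object.__setattr__(self, "slice_sum", s)
        object.__setattr__(self, "slice_percent", s / 16.0 * 100.0)

    @classmethod
    def from_grades(
        cls, grades: Sequence[QuadrantGrade] | Mapping[str, int] | Sequence[int]
    ) -> "SliceAssessment":
        return cls(grades=_as_quadrant_grades(grades))

    def grade_of(self, quadrant: str) -> int:
        for g in self.grades:
            if g.quadrant == quadrant:
                return g.grade
        raise GradingError(f"unknown quadrant {quadrant!r}")


@dataclass(frozen=True)
class SegmentAssessment:
    """Per-segment fibrosis: ``n`` slices averaged to one percentage.

    The segment percentage is the arithmetic mean of the per-slice
    percentages, equivalently ``sum(slice sums) / (16 n) * 100``.
    """

    slices: tuple[SliceAssessment, ...]
    n_slices: int = field(init=False)
    segment_percent: float = field(init=False)

    def __post_init__(self) -> None:
        slices = tuple(self.slices)
        if not slices:
            raise GradingError("a segment needs at least one slice")
        object.__setattr__(self, "slices", slices)
        object.__setattr__(self, "n_slices", len(slices))
        object.__setattr__(
            self,
            "segment_percent",
            sum(s.slice_percent for s in slices) / len(slices),
        )

    @property
    def total_score(self) -> int:
        """Sum of slice sums across the segment (the condensed study score)."""
        return sum(s.slice_sum for s in self.slices)


def grade_from_fraction(
    fraction: float, trace_threshold: float = DEFAULT_TRACE_THRESHOLD
) -> int:
    """Map a continuous affected fraction of a quadrant to the 0-4 grade.

    Bin boundaries follow the printed scale labels (1-25 %, 26-50 %, 51-75 %,
    76-100 %): the upper endpoints 0.25, 0.50 and 0.75 belong to the lower
    grade.  Fractions at or below ``trace_threshold`` count as grade 0
    ("no/trace").

    Parameters
    ----------
    fraction
        Affected fraction of the quadrant, in [0, 1].
    trace_threshold
        Largest fraction still considered "trace"; must be < 0.25 so that
        grade 1 remains reachable.  Default 0.005 (0.5 % of the quadrant).
    """
    if not 0.0 <= fraction <= 1.0:
        raise GradingError(f"fraction must be in [0, 1], got {fraction}")
    if not 0.0 <= trace_threshold < 0.25:
        raise GradingError(
            "trace_threshold must be in [0, 0.25); "
            f"{trace_threshold} would swallow grade 1"
        )
    if fraction <= trace_threshold:
        return 0
    for g in (1, 2, 3):
        if fraction <= g / 4.0:
            return g
    return 4


def slice_sum_score(
    grades: Sequence[QuadrantGrade] | Mapping[str, int] | Sequence[int],
) -> int:
    """Sum of the four quadrant grades, an integer in 0..16."""
    return sum(g.grade for g in _as_quadrant_grades(grades))


def slice_percent(
    grades: Sequence[QuadrantGrade] | Mapping[str, int] | Sequence[int],
) -> float:
    """Percentage of the slice affected: ``sum(grades) / 16 * 100``.

    Always a multiple of 6.25 in [0, 100]; e.g. a slice sum of 2 is 12.5 %
    and the saturated slice (4,4,4,4) is 100 %.
    """
    return slice_sum_score(grades) / 16.0 * 100.0


def segment_percent(slice_percents: Iterable[float], n: int | None = None) -> float:
    """Mean per-slice percentage over the slices covering an operative level.

    Parameters
    ----------
    slice_percents
        Per-slice fibrosis percentages, each in [0, 100].
    n
        Expected number of slices; if given, a mismatch with the list length
        is an error (guards against dropped slices in a fixed-protocol study).
    """
    values = [float(p) for p in slice_percents]
    if not values:
        raise GradingError("segment_percent needs at least one slice")
    if n is not None and len(values) != n:
        raise GradingError(f"expected {n} slices, got {len(values)}")
    for p in values:
        if not 0.0 <= p <= 100.0:
            raise GradingError(f"slice percent out of [0, 100]: {p}")
    return sum(values) / len(values)
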