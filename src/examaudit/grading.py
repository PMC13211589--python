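"""Discrepancy-based partial-credit grading and 20-point exam normalization.

A *discrepancy* is one element of the symmetric difference between the
selected option set and the answer key — a distractor wrongly selected, or
a correct option omitted.  The faculty rubric awards full credit for a
perfect match, half credit for one discrepancy, a fifth for two, and
nothing beyond that; the fractions scale with the item's ``max_points`` so
that normalized scores stay in [0, 1].  Exam totals are normalized to a
20-point scale with a pass mark of 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import (
    Question,
    QuestionFormat,
    ResponseRecord,
    SchemaError,
    Thresholds,
)

__all__ = [
    "Rubric",
    "GradedResponse",
    "ExamScore",
    "count_discrepancies",
    "partial_credit",
    "grade_response",
    "grade_all",
    "exam_score_20",
]


@dataclass(frozen=True)
class Rubric:
    """Partial-credit fractions of ``max_points`` by discrepancy count.

    ``sba_all_or_nothing`` zeroes any wrong single-best-answer instead of
    applying the fractional rubric (off by default: a wrong SBA counts as
    2 discrepancies and earns the two-discrepancy fraction).
    """

    full: float = 1.0
    one_discrepancy: float = 0.5
    two_discrepancies: float = 0.2
    beyond: float = 0.0
    sba_all_or_nothing: bool = False

    def fraction(self, discrepancies: int) -> float:
        if discrepancies < 0:
            raise ValueError("discrepancy count cannot be negative")
        if discrepancies == 0:
            return self.full
        if discrepancies == 1:
            return self.one_discrepancy
        if discrepancies == 2:
            return self.two_discrepancies
        return self.beyond


DEFAULT_RUBRIC = Rubric()


@dataclass(frozen=True)
class GradedResponse:
    responder_id: str
    question_id: str
    discrepancies: int
    points: float
    normalized: float  # points / max_points, in [0, 1]


@dataclass(frozen=True)
class ExamScore:
    responder_id: str
    score_20: float
    passed: bool
    total_points: float
    total_max: float


def count_discrepancies(
    key: Iterable[str],
    selected: Iterable[str],
    options: Iterable[str] | None = None,
) -> int:
    """Count discrepancies: ``|key symmetric-difference selected|``.

    An empty selection (abstention) therefore costs ``len(key)``
    discrepancies.  When ``options`` is given, selections outside the option
    universe are rejected.
    """
    key_set = frozenset(key)
    sel_set = frozenset(selected)
    if options is not None:
        universe = frozenset(options)
        stray = sel_set - universe
        if stray:
            raise SchemaError(
                f"selected labels {sorted(stray)} outside the option universe"
            )
        if not key_set <= universe:
            raise SchemaError("key labels outside the option universe")
    return len(key_set ^ sel_set)


def partial_credit(
    discrepancies: int,
    max_points: float = 1.0,
    rubric: Rubric = DEFAULT_RUBRIC,
) -> float:
    """Points awarded for a given discrepancy count on a ``max_points`` item."""
    if max_points <= 0:
        raise ValueError("max_points must be positive")
    return rubric.fraction(discrepancies) * max_points


def grade_response(
    question: Question,
    record: ResponseRecord,
    rubric: Rubric = DEFAULT_RUBRIC,
) -> GradedResponse:
    """Grade one response against the official key.

    MCQ-like items go through the discrepancy rubric; SAQ items pass their
    pre-assigned ``graded_points`` through (capped checking only).
    """
    if record.question_id != question.question_id:
        raise ValueError(
            f"record for {record.question_id!r} graded against "
            f"{question.question_id!r}"
        )
    if question.format is QuestionFormat.SAQ:
        if record.graded_points is None:
            raise SchemaError(
                f"SAQ response ({record.responder_id}, {record.question_id}) "
                "has no graded_points"
            )
        points = record.graded_points
        if points > question.max_points + 1e-9:
            raise SchemaError(
                f"graded_points {points} exceed max_points {question.max_points}"
            )
        return GradedResponse(
            responder_id=record.responder_id,
            question_id=record.question_id,
            discrepancies=0 if points == question.max_points else 1,
            points=points,
            normalized=points / question.max_points,
        )
    if record.selected is None:
        raise SchemaError(
            f"{question.format.value} response ({record.responder_id}, "
            f"{record.question_id}) has no selected options"
        )
    d = count_discrepancies(question.key, record.selected, question.options)
    if question.format is QuestionFormat.SBA and rubric.sba_all_or_nothing:
        points = question.max_points if d == 0 else 0.0
    else:
        points = partial_credit(d, question.max_points, rubric)
    return GradedResponse(
        responder_id=record.responder_id,
        question_id=record.question_id,
        discrepancies=d,
        points=points,
        normalized=points / question.max_points,
    )


def grade_all(
    questions: Mapping[str, Question] | Iterable[Question],
    records: Iterable[ResponseRecord],
    rubric: Rubric = DEFAULT_RUBRIC,
) -> tuple[GradedResponse, ...]:
    """Grade a batch of responses; unknown question ids raise."""
    if not isinstance(questions, Mapping):
        questions = {q.question_id: q for q in questions}
    out = []
    for rec in records:
        if rec.question_id not in questions:
            raise KeyError(f"response references unknown question {rec.question_id!r}")
        out.append(grade_response(questions[rec.question_id], rec, rubric))
    return tuple(out)


def exam_score_20(
    graded: Sequence[GradedResponse],
    questions: Mapping[str, Question] | Iterable[Question],
    pass_mark: float | None = None,
    thresholds: Thresholds | None = None,
) -> ExamScore:
    """Normalize one responder's graded answers to the 20-point scale.

    ``20 * sum(points) / sum(max_points)`` over exactly the given questions;
    the pass flag is ``score >= pass_mark`` (the boundary passes).
    """
    if not isinstance(questions, Mapping):
        questions = {q.question_id: q for q in questions}
    if pass_mark is None:
        pass_mark = (thresholds or Thresholds()).pass_mark
    responders = {g.responder_id for g in graded}
    if len(responders) != 1:
        raise ValueError(
            f"exam_score_20 expects one responder, got {sorted(responders)}"
        )
    seen = [g.question_id for g in graded]
    if len(set(seen)) != len(seen):
        raise ValueError("duplicate graded records for one question")
    missing = sorted(set(questions) - set(seen))
    if missing:
        raise ValueError(f"missing graded responses for questions {missing}")
    extra = sorted(set(seen) - set(questions))
    if extra:
        raise ValueError(f"graded responses for unknown questions {extra}")
    total = sum(g.points for g in graded)
    total_max = sum(q.max_points for q in questions.values())
    score = 20.0 * total / total_max
    return ExamScore(
        responder_id=next(iter(responders)),
        score_20=score,
        passed=score >= pass_mark,
        total_points=total,
        total_max=total_max,
    )
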