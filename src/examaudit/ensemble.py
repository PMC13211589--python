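"""Per-question ensemble summaries and elbow-point threshold detection.

For each item the model ensemble yields three headline metrics — the mean of
the models' normalized scores (S_i), their dispersion, and the number of
models that failed to answer correctly — plus the number of *distinct* wrong
answers (multiple models converging on the same wrong answer signals a
shared misconception, not ambiguity) and the count of ambiguity
self-reports.

``elbow_threshold`` supports data-driven threshold choice: it finds the
point of maximum perpendicular distance to the chord of the sorted metric
curve (a Kneedle-style knee), i.e. the transition from typical to anomalous
values.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grading import GradedResponse
from .model import Question, QuestionMetrics, ResponderKind, ResponseRecord

__all__ = [
    "summarize_question",
    "summarize_all",
    "elbow_threshold",
    "metrics_to_frame",
    "metrics_from_frame",
]

_WS = re.compile(r"\s+")


def _answer_signature(record: ResponseRecord, graded: GradedResponse) -> object:
    """Canonical form of a wrong answer, used to count distinct wrong answers.

    MCQ-like: the selected option set.  SAQ: the whitespace/case-normalized
    answer text, falling back to the graded points when no text is present.
    """
    if record.selected is not None:
        return frozenset(record.selected)
    if record.answer_text:
        return _WS.sub(" ", record.answer_text.strip().casefold())
    return round(graded.normalized, 9)


def summarize_question(
    question: Question,
    graded: Sequence[GradedResponse],
    records: Sequence[ResponseRecord],
    sd_estimator: str = "sample",
    incorrect_cutoff: float = 1.0,
) -> QuestionMetrics:
    """Summarize the model ensemble's behavior on one question.

    ``graded`` and ``records`` are the *model* responders' graded scores and
    raw records for this question (students are the caller's concern to
    filter).  A model counts as incorrect when its normalized score is
    strictly below ``incorrect_cutoff`` (default 1.0: any discrepancy).

    ``sd_estimator``: "sample" (n-1 denominator, default) or "population".
    """
    graded = [g for g in graded if g.question_id == question.question_id]
    records = [
        r
        for r in records
        if r.question_id == question.question_id
        and r.responder_kind is ResponderKind.model
    ]
    if not graded:
        raise ValueError(f"no model responses for question {question.question_id!r}")
    by_responder = {r.responder_id: r for r in records}
    if set(g.responder_id for g in graded) != set(by_responder):
        raise ValueError(
            f"graded responders and response records disagree for "
            f"question {question.question_id!r}"
        )
    # sorted so the reduction order (hence the last-ulp rounding) does not
    # depend on responder order
    scores = np.sort(np.array([g.normalized for g in graded], dtype=float))
    n = len(scores)
    if n == 1:
        sd = 0.0
    elif sd_estimator == "sample":
        sd = float(np.std(scores, ddof=1))
    elif sd_estimator == "population":
        sd = float(np.std(scores, ddof=0))
    else:
        raise ValueError(f"unknown sd_estimator {sd_estimator!r}")
    wrong = [g for g in graded if g.normalized < incorrect_cutoff]
    signatures = {
        _answer_signature(by_responder[g.responder_id], g) for g in wrong
    }
    n_reports = sum(bool(r.ambiguity_report) for r in records)
    return QuestionMetrics(
        question_id=question.question_id,
        mean_score=float(np.mean(scores)),
        sd_score=sd,
        n_incorrect=len(wrong),
        n_distinct_wrong=len(signatures),
        n_ambiguity_reports=n_reports,
        n_models=n,
    )


def summarize_all(
    questions: Iterable[Question],
    graded: Sequence[GradedResponse],
    records: Sequence[ResponseRecord],
    sd_estimator: str = "sample",
    incorrect_cutoff: float = 1.0,
) -> tuple[QuestionMetrics, ...]:
    """Summarize every question in turn (model responders only)."""
    model_ids = {
        r.responder_id for r in records if r.responder_kind is ResponderKind.model
    }
    model_graded = [g for g in graded if g.responder_id in model_ids]
    return tuple(
        summarize_question(q, model_graded, records, sd_estimator, incorrect_cutoff)
        for q in questions
    )


def elbow_threshold(
    values: Iterable[float],
    flatness_tol: float = 0.02,
) -> float | None:
    """Find the knee of a sorted metric distribution.

    Sorts values in descending order, min-max normalizes both axes, and
    returns the value at maximum perpendicular distance from the chord
    joining the first and last sorted points.  Returns ``None`` when the
    curve is too flat (maximum distance below ``flatness_tol`` in normalized
    units — e.g. an exactly linear sequence has no knee).  Ties break toward
    the earlier sorted index.
    """
    vals = np.asarray(sorted(values, reverse=True), dtype=float)
    if vals.size < 3:
        raise ValueError("elbow detection needs at least 3 values")
    span = vals[0] - vals[-1]
    if span == 0:
        return None
    x = np.linspace(0.0, 1.0, vals.size)
    y = (vals - vals[-1]) / span
    # perpendicular distance to the chord from (0, y0) to (1, y_last);
    # after normalization the chord runs (0, 1) -> (1, 0)
    dist = np.abs(x + y - 1.0) / np.sqrt(2.0)
    idx = int(np.argmax(dist))
    if dist[idx] < flatness_tol:
        return None
    return float(vals[idx])


_METRIC_COLS = [
    "question_id",
    "mean_score",
    "sd_score",
    "n_incorrect",
    "n_distinct_wrong",
    "n_ambiguity_reports",
    "n_models",
]


def metrics_to_frame(metrics: Sequence[QuestionMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(m, c) for c in _METRIC_COLS} for m in metrics],
        columns=_METRIC_COLS,
    )


def metrics_from_frame(df: pd.DataFrame | Mapping) -> tuple[QuestionMetrics, ...]:
    df = pd.DataFrame(df)
    return tuple(
        QuestionMetrics(
            question_id=str(row["question_id"]),
            mean_score=float(row["mean_score"]),
            sd_score=float(row["sd_score"]),
            n_incorrect=int(row["n_incorrect"]),
            n_distinct_wrong=int(row["n_distinct_wrong"]),
            n_ambiguity_reports=int(row["n_ambiguity_reports"]),
            n_models=int(row["n_models"]),
        )
        for _, row in df.iterrows()
    )
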