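"""The four binary diagnostic tags and the composite ambiguity score.

Tag criteria (all comparisons strict where written as strict):

* **ambiguity** — at least 2 models answered incorrectly AND gave at least
  2 distinct wrong answers (diverse wrong answers suggest multiple plausible
  readings; convergence on one wrong answer is a shared misconception).
* **low_performance** — ensemble mean score below 0.5 AND SD below 0.3
  (uniformly poor: potentially unanswerable or structurally flawed).
* **incoherence** — SD above 0.3 (divergent understanding of the item).
* **subjective_ambiguity** — at least 2 models self-reported ambiguity.

low_performance and incoherence depend on opposing SD thresholds and are
mutually exclusive, so the composite score A_i (the sum of the four tags)
ranges 0–3: 0 "No issues detected", 1 "Minor concern", 2 "Moderate
ambiguity", 3 "Strong signal of item flaw or misleading structure".
"""

from __future__ import annotations

import decimal
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .model import QuestionMetrics, Thresholds

__all__ = [
    "TagVector",
    "UnreachableScoreError",
    "assign_tags",
    "assign_all",
    "score_label",
    "tag_combinations",
    "round_half_up",
]

TAG_NAMES = ("ambiguity", "low_performance", "incoherence", "subjective_ambiguity")

SCORE_LABELS = {
    0: "No issues detected",
    1: "Minor concern",
    2: "Moderate ambiguity",
    3: "Strong signal of item flaw or misleading structure",
}


class UnreachableScoreError(RuntimeError):
    """Tripwire: a composite score above 3 was produced.

    The tag criteria make scores above 3 impossible (the two SD-based tags
    are mutually exclusive); reaching this error means the engine is broken.
    """


@dataclass(frozen=True)
class TagVector:
    question_id: str
    ambiguity: int
    low_performance: int
    incoherence: int
    subjective_ambiguity: int
    ambiguity_score: int

    def __post_init__(self) -> None:
        for name in TAG_NAMES:
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"tag {name} must be binary")
        if self.low_performance and self.incoherence:
            raise ValueError(
                "low_performance and incoherence are mutually exclusive"
            )
        total = sum(getattr(self, name) for name in TAG_NAMES)
        if self.ambiguity_score != total:
            raise ValueError("ambiguity_score must equal the sum of the tags")
        if self.ambiguity_score > 3:
            raise UnreachableScoreError(
                f"composite ambiguity score {self.ambiguity_score} > 3 "
                f"for question {self.question_id!r}"
            )

    @property
    def tags(self) -> frozenset[str]:
        return frozenset(n for n in TAG_NAMES if getattr(self, n))


def assign_tags(metrics: QuestionMetrics, thresholds: Thresholds | None = None) -> TagVector:
    """Evaluate the four tag criteria on one question's ensemble metrics."""
    t = thresholds or Thresholds()
    ambiguity = int(
        metrics.n_incorrect >= t.min_wrong_models
        and metrics.n_distinct_wrong >= t.min_distinct_wrong
    )
    low_performance = int(
        metrics.mean_score < t.low_perf_mean and metrics.sd_score < t.sd_split
    )
    incoherence = int(metrics.sd_score > t.sd_split)
    subjective = int(metrics.n_ambiguity_reports >= t.min_ambiguity_reports)
    score = ambiguity + low_performance + incoherence + subjective
    return TagVector(
        question_id=metrics.question_id,
        ambiguity=ambiguity,
        low_performance=low_performance,
        incoherence=incoherence,
        subjective_ambiguity=subjective,
        ambiguity_score=score,
    )


def assign_all(
    metrics: Iterable[QuestionMetrics],
    thresholds: Thresholds | None = None,
) -> tuple[TagVector, ...]:
    return tuple(assign_tags(m, thresholds) for m in metrics)


def score_label(ambiguity_score: int) -> str:
    """Qualitative label for a composite ambiguity score."""
    try:
        return SCORE_LABELS[int(ambiguity_score)]
    except KeyError:
        raise UnreachableScoreError(
            f"no label for composite score {ambiguity_score}"
        ) from None


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the usual reporting convention)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def tag_combinations(tags: Sequence[TagVector]) -> pd.DataFrame:
    """Frequency table of distinct tag subsets across items.

    Returns columns ``combination`` (``+``-joined sorted tag names, empty
    string for untagged items), ``count``, and ``percent`` of all items,
    rounded half-up to one decimal.  Empty input yields an empty table.
    """
    counts = Counter(tuple(sorted(t.tags)) for t in tags)
    total = len(tags)
    rows = [
        {
            "combination": "+".join(combo),
            "count": n,
            "percent": round_half_up(100.0 * n / total, 1),
        }
        for combo, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["combination", "count", "percent"])


_TAG_COLS = ["question_id", *TAG_NAMES, "ambiguity_score"]


def tags_to_frame(tags: Sequence[TagVector]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(t, c) for c in _TAG_COLS} for t in tags], columns=_TAG_COLS
    )


def tags_from_frame(df: pd.DataFrame) -> tuple[TagVector, ...]:
    return tuple(
        TagVector(
            question_id=str(row["question_id"]),
            ambiguity=int(row["ambiguity"]),
            low_performance=int(row["low_performance"]),
            incoherence=int(row["incoherence"]),
            subjective_ambiguity=int(row["subjective_ambiguity"]),
            ambiguity_score=int(row["ambiguity_score"]),
        )
        for _, row in df.iterrows()
    )
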