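"""Ambiguity-weighted quality scores for docimological components.

Each question gets a quality score ``Q_i = 20 * S_i`` where S_i is the
ensemble mean normalized score, and a weight ``w_i = 1 / (1 + A_i)`` that
down-weights ambiguous items (A_i is the composite ambiguity score, 0–3, so
w_i is 1, 1/2, 1/3 or 1/4).  The component score is the w-weighted mean of
the Q_i, banded qualitatively:

    [18, 20] excellent | [15, 18) very good | [12, 15) moderate
    | [10, 12) poor | [0, 10) insufficient

Components scoring below 15 are flagged for author re-review (the boundary
score of 15 is not flagged, hence 15 belongs to the upper band).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import ComponentSpec, QuestionMetrics, Thresholds
from .tagging import TagVector

__all__ = [
    "ComponentQuality",
    "question_quality",
    "ambiguity_weight",
    "component_score",
    "band",
    "assess_component",
    "assess_all",
    "BANDS",
]

# (lower, upper, label); [lower, upper) except the top band, closed at 20
BANDS = (
    (18.0, 20.0, "excellent"),
    (15.0, 18.0, "very_good"),
    (12.0, 15.0, "moderate"),
    (10.0, 12.0, "poor"),
    (0.0, 10.0, "insufficient"),
)


def question_quality(mean_score: float) -> float:
    """Q_i = 20 * S_i, mapping the ensemble mean onto the 20-point scale."""
    if not (0.0 <= mean_score <= 1.0 + 1e-12):
        raise ValueError(f"mean score {mean_score} outside [0, 1]")
    return 20.0 * min(mean_score, 1.0)


def ambiguity_weight(ambiguity_score: int) -> float:
    """w_i = 1 / (1 + A_i)."""
    a = int(ambiguity_score)
    if not (0 <= a <= 3):
        raise ValueError(f"ambiguity score {a} outside [0, 3]")
    return 1.0 / (1.0 + a)


def component_score(Q: Sequence[float], w: Sequence[float]) -> float:
    """Weighted mean of question quality scores: sum(Q_i w_i) / sum(w_i)."""
    Q = np.asarray(Q, dtype=float)
    w = np.asarray(w, dtype=float)
    if Q.size == 0:
        raise ValueError("component has no questions")
    if Q.shape != w.shape:
        raise ValueError("quality and weight collections differ in length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(Q * w) / np.sum(w))


def band(score: float) -> str:
    """Qualitative band for a 20-point component score."""
    if not (-1e-9 <= score <= 20.0 + 1e-9):
        raise ValueError(f"score {score} outside the 20-point scale")
    score = min(max(score, 0.0), 20.0)
    for lower, upper, label in BANDS:
        if score >= lower:
            return label
    return "insufficient"


@dataclass(frozen=True)
class ComponentQuality:
    component_id: str
    question_ids: tuple[str, ...]
    question_quality: tuple[float, ...]  # Q_i, 20-point scale
    ambiguity_scores: tuple[int, ...]  # A_i
    weights: tuple[float, ...]  # w_i = 1/(1+A_i)
    component_score: float
    band: str
    needs_review: bool

    def as_dict(self) -> dict:
        return {
            "component_id": self.component_id,
            "question_ids": list(self.question_ids),
            "question_quality": list(self.question_quality),
            "ambiguity_scores": list(self.ambiguity_scores),
            "weights": list(self.weights),
            "component_score": self.component_score,
            "band": self.band,
            "needs_review": self.needs_review,
        }


def assess_component(
    component: ComponentSpec,
    metrics: Mapping[str, QuestionMetrics],
    tags: Mapping[str, TagVector],
    thresholds: Thresholds | None = None,
) -> ComponentQuality:
    """Compute the weighted quality score and band for one component."""
    t = thresholds or Thresholds()
    missing = [q for q in component.question_ids if q not in metrics or q not in tags]
    if missing:
        raise KeyError(
            f"component {component.component_id}: no metrics/tags for {missing}"
        )
    Q = tuple(question_quality(metrics[q].mean_score) for q in component.question_ids)
    A = tuple(tags[q].ambiguity_score for q in component.question_ids)
    w = tuple(ambiguity_weight(a) for a in A)
    score = component_score(Q, w)
    return ComponentQuality(
        component_id=component.component_id,
        question_ids=component.question_ids,
        question_quality=Q,
        ambiguity_scores=A,
        weights=w,
        component_score=score,
        band=band(score),
        needs_review=score < t.review_cutoff,
    )


def assess_all(
    components: Sequence[ComponentSpec],
    metrics: Sequence[QuestionMetrics],
    tags: Sequence[TagVector],
    thresholds: Thresholds | None = None,
) -> tuple[ComponentQuality, ...]:
    mmap = {m.question_id: m for m in metrics}
    tmap = {t.question_id: t for t in tags}
    return tuple(
        assess_component(c, mmap, tmap, thresholds) for c in components
    )
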