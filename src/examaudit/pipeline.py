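"""End-to-end orchestration: grade -> metrics -> tag -> quality -> compare.

``run_pipeline`` composes the stage operations exactly as they would be
called by hand, collects warnings, and produces a deterministic report
(JSON for machines, Markdown for humans).  Rerunning with identical inputs
and configuration reproduces byte-identical JSON.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import stats as cohort_stats
from .ensemble import metrics_to_frame, summarize_all
from .grading import Rubric, exam_score_20, grade_all
from .model import (
    QuestionBank,
    QuestionMetrics,
    ResponderKind,
    ResponseRecord,
    Thresholds,
    merge_duplicate_responses,
)
from .quality import ComponentQuality, assess_all
from .tagging import (
    TagVector,
    assign_all,
    score_label,
    tag_combinations,
    tags_to_frame,
)

__all__ = ["PipelineRun", "run_pipeline", "report_json", "report_markdown"]


@dataclass(frozen=True)
class PipelineRun:
    """All stage outputs of one audit run."""

    metrics: tuple[QuestionMetrics, ...]
    tags: tuple[TagVector, ...]
    quality: tuple[ComponentQuality, ...]
    tag_table: object  # DataFrame: combination / count / percent
    exam_scores: dict  # responder_id -> 20-point exam score
    comparison: cohort_stats.ComparisonResult | None
    warnings: tuple[str, ...]
    thresholds: Thresholds


def run_pipeline(
    bank: QuestionBank,
    records: Sequence[ResponseRecord],
    thresholds: Thresholds | None = None,
    rubric: Rubric | None = None,
    sd_estimator: str = "sample",
    incorrect_cutoff: float = 1.0,
    input_format: str | None = None,
) -> PipelineRun:
    """Run the full audit on a bank and its response records."""
    thresholds = thresholds or Thresholds()
    rubric = rubric or Rubric()
    caught: list[str] = []

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    records = stage("ingest", merge_duplicate_responses, records, input_format)
    questions = bank.by_id
    graded = stage("grade", grade_all, questions, records, rubric)
    model_records = [r for r in records if r.responder_kind is ResponderKind.model]
    metrics = stage(
        "metrics",
        summarize_all,
        bank.questions,
        graded,
        model_records,
        sd_estimator,
        incorrect_cutoff,
    )
    tags = stage("tag", assign_all, metrics, thresholds)
    quality = stage("quality", assess_all, bank.components, metrics, tags, thresholds)
    tag_table = stage("tag", tag_combinations, tags)

    # per-responder exam scores on the 20-point scale
    by_responder: dict[str, list] = {}
    kinds: dict[str, ResponderKind] = {}
    for rec, g in zip(records, graded):
        by_responder.setdefault(rec.responder_id, []).append(g)
        kinds[rec.responder_id] = rec.responder_kind
    exam_scores = {
        rid: exam_score_20(gs, questions, thresholds=thresholds).score_20
        for rid, gs in by_responder.items()
        if len(gs) == len(questions)
    }
    student_scores = [
        v for k, v in exam_scores.items() if kinds[k] is ResponderKind.student
    ]
    model_scores = [
        v for k, v in exam_scores.items() if kinds[k] is ResponderKind.model
    ]
    comparison = None
    if len(student_scores) >= 3 and len(model_scores) >= 3:
        with _warnings.catch_warnings(record=True) as wlist:
            _warnings.simplefilter("always")
            comparison = cohort_stats.compare(
                model_scores, student_scores, labels=("models", "students")
            )
        caught.extend(str(w.message) for w in wlist)
    return PipelineRun(
        metrics=tuple(metrics),
        tags=tuple(tags),
        quality=tuple(quality),
        tag_table=tag_table,
        exam_scores=exam_scores,
        comparison=comparison,
        warnings=tuple(caught),
        thresholds=thresholds,
    )


def report_json(run: PipelineRun) -> str:
    """Deterministic JSON report (sorted keys, fixed separators)."""
    payload = {
        "questions": [
            {
                "question_id": m.question_id,
                "mean_score": m.mean_score,
                "sd_score": m.sd_score,
                "n_incorrect": m.n_incorrect,
                "n_distinct_wrong": m.n_distinct_wrong,
                "n_ambiguity_reports": m.n_ambiguity_reports,
                "tags": sorted(t.tags),
                "ambiguity_score": t.ambiguity_score,
                "label": score_label(t.ambiguity_score),
            }
            for m, t in zip(run.metrics, run.tags)
        ],
        "components": [q.as_dict() for q in run.quality],
        "tag_combinations": run.tag_table.to_dict(orient="records"),
        "comparison": (
            None
            if run.comparison is None
            else {
                "groups": [run.comparison.label_a, run.comparison.label_b],
                "n": [run.comparison.n_a, run.comparison.n_b],
                "test_used": run.comparison.test_used,
                "statistic": run.comparison.statistic,
                "p_value": run.comparison.p_value,
                "significant": run.comparison.significant,
            }
        ),
        "warnings": list(run.warnings),
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def report_markdown(run: PipelineRun) -> str:
    lines = ["# Exam audit report", "", "## Components", ""]
    lines += [
        "| component | score /20 | band | needs review |",
        "|---|---|---|---|",
    ]
    for q in run.quality:
        lines.append(
            f"| {q.component_id} | {q.component_score:.2f} | {q.band} | "
            f"{'yes' if q.needs_review else 'no'} |"
        )
    lines += ["", "## Flagged questions", ""]
    lines += [
        "| question | score | tags | label |",
        "|---|---|---|---|",
    ]
    for t in run.tags:
        if t.ambiguity_score > 0:
            lines.append(
                f"| {t.question_id} | {t.ambiguity_score} | "
                f"{'+'.join(sorted(t.tags))} | {score_label(t.ambiguity_score)} |"
            )
    lines += ["", "## Tag combinations", ""]
    lines += ["| combination | count | % |", "|---|---|---|"]
    for row in run.tag_table.itertuples():
        lines.append(f"| {row.combination or '(none)'} | {row.count} | {row.percent} |")
    if run.comparison is not None:
        c = run.comparison
        lines += [
            "",
            "## Models vs students",
            "",
            f"{c.test_used}: statistic {c.statistic:.3f}, p = {c.p_value:.4f} "
            f"({'significant' if c.significant else 'not significant'} at .05)",
        ]
    if run.warnings:
        lines += ["", "## Warnings", ""] + [f"- {w}" for w in run.warnings]
    return "\n".join(lines) + "\n"
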