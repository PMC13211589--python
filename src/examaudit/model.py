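"""Domain types, validation, and tabular readers/writers.

The exam universe is a *question bank*: docimological components (blocks of
an exam sharing one format — progressive clinical cases, mini-PCC, key
feature problems, isolated question sequences) made of individual items
(multi-select MCQ, single-best-answer, extended matching, or pre-graded
short-answer questions).  Responders are either students or members of a
model ensemble; model responders additionally carry a binary self-reported
ambiguity flag per item.

Serialization conventions (defined by this package):

* one CSV table each for questions, components, and responses, UTF-8 with a
  mandatory header row;
* multi-valued cells (option lists, keys, selections) use ``|`` as the
  separator; the empty string is the empty set;
* option labels are case-sensitive opaque tokens, stripped of surrounding
  whitespace only;
* a JSON dialect bundles questions and components into a single object
  ``{"questions": [...], "components": [...]}``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SchemaError",
    "QuestionFormat",
    "ComponentType",
    "ResponderKind",
    "Question",
    "ComponentSpec",
    "ResponseRecord",
    "QuestionMetrics",
    "Thresholds",
    "QuestionBank",
    "read_question_bank",
    "write_question_bank",
    "read_responses",
    "write_responses",
    "write_report",
]

SEP = "|"


class SchemaError(ValueError):
    """A record violates the documented schema or a domain invariant."""


class QuestionFormat(str, enum.Enum):
    MCQ = "MCQ"  # multi-select multiple choice
    SBA = "SBA"  # single best answer
    EMQ = "EMQ"  # extended matching
    SAQ = "SAQ"  # short answer, graded externally


class ComponentType(str, enum.Enum):
    PCC = "PCC"
    mPCC = "mPCC"
    KFP = "KFP"
    IQS = "IQS"


class ResponderKind(str, enum.Enum):
    student = "student"
    model = "model"


_MCQ_LIKE = (QuestionFormat.MCQ, QuestionFormat.SBA, QuestionFormat.EMQ)


def _clean_token(tok: str) -> str:
    return str(tok).strip()


def _parse_multi(cell: object) -> frozenset[str]:
    """Parse a ``|``-separated cell into a set of option labels."""
    if cell is None:
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(_clean_token(t) for t in text.split(SEP) if t.strip())


def _fmt_multi(values: Iterable[str]) -> str:
    return SEP.join(sorted(values))


@dataclass(frozen=True)
class Question:
    """One exam item with its option universe and official answer key."""

    question_id: str
    component_id: str
    format: QuestionFormat
    options: tuple[str, ...]
    key: frozenset[str]
    max_points: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "format", QuestionFormat(self.format))
        object.__setattr__(
            self, "options", tuple(_clean_token(o) for o in self.options)
        )
        object.__setattr__(
            self, "key", frozenset(_clean_token(k) for k in self.key)
        )
        if not self.question_id:
            raise SchemaError("question_id must be non-empty")
        if len(set(self.options)) != len(self.options):
            raise SchemaError(
                f"question {self.question_id}: duplicate option labels"
            )
        if not (self.max_points > 0):
            raise SchemaError(
                f"question {self.question_id}: max_points must be positive"
            )
        if self.format is QuestionFormat.SAQ:
            if self.options or self.key:
                raise SchemaError(
                    f"question {self.question_id}: SAQ items carry no options/key"
                )
            return
        if len(self.options) < 2:
            raise SchemaError(
                f"question {self.question_id}: {self.format.value} needs >=2 options"
            )
        if not self.key <= set(self.options):
            bad = sorted(self.key - set(self.options))
            raise SchemaError(
                f"question {self.question_id}: key labels {bad} not among options"
            )
        if not self.key:
            raise SchemaError(f"question {self.question_id}: empty answer key")
        if self.format is QuestionFormat.SBA and len(self.key) != 1:
            raise SchemaError(
                f"question {self.question_id}: SBA key must have exactly 1 option"
            )

    @property
    def is_mcq_like(self) -> bool:
        return self.format in _MCQ_LIKE


@dataclass(frozen=True)
class ComponentSpec:
    """A docimological component: an ordered block of question ids."""

    component_id: str
    dtype: ComponentType
    question_ids: tuple[str, ...]
    author_specialty: str | None = None  # intensivist | emergency
    author_rank: str | None = None  # clinical_fellow | associate_professor | full_professor
    cohort_label: str | None = None

    _SPECIALTIES = ("intensivist", "emergency")
    _RANKS = ("clinical_fellow", "associate_professor", "full_professor")

    def __post_init__(self) -> None:
        object.__setattr__(self, "dtype", ComponentType(self.dtype))
        object.__setattr__(self, "question_ids", tuple(self.question_ids))
        if not self.question_ids:
            raise SchemaError(f"component {self.component_id}: no questions")
        if len(set(self.question_ids)) != len(self.question_ids):
            raise SchemaError(
                f"component {self.component_id}: duplicate question ids"
            )
        if self.author_specialty is not None and self.author_specialty not in self._SPECIALTIES:
            raise SchemaError(
                f"component {self.component_id}: unknown specialty {self.author_specialty!r}"
            )
        if self.author_rank is not None and self.author_rank not in self._RANKS:
            raise SchemaError(
                f"component {self.component_id}: unknown rank {self.author_rank!r}"
            )


@dataclass(frozen=True)
class ResponseRecord:
    """One responder's answer to one question.

    MCQ-like items carry ``selected`` (possibly empty: an abstention); SAQ
    items carry pre-graded ``graded_points`` and optionally the raw
    ``answer_text``.  ``ambiguity_report`` is the model's self-declared flag
    that the item is ambiguous; students never carry it.
    """

    responder_id: str
    responder_kind: ResponderKind
    question_id: str
    selected: frozenset[str] | None = None
    graded_points: float | None = None
    answer_text: str | None = None
    ambiguity_report: bool = False
    input_format: str | None = None  # full_context | sequential

    def __post_init__(self) -> None:
        object.__setattr__(self, "responder_kind", ResponderKind(self.responder_kind))
        if self.selected is not None:
            object.__setattr__(self, "selected", frozenset(self.selected))
        if (self.selected is None) == (self.graded_points is None):
            raise SchemaError(
                f"response ({self.responder_id}, {self.question_id}): exactly one "
                "of selected / graded_points must be populated"
            )
        if self.graded_points is not None and self.graded_points < 0:
            raise SchemaError(
                f"response ({self.responder_id}, {self.question_id}): negative points"
            )
        if self.responder_kind is ResponderKind.student and self.ambiguity_report:
            raise SchemaError(
                f"response ({self.responder_id}, {self.question_id}): students "
                "cannot carry an ambiguity self-report"
            )
        if self.input_format is not None and self.input_format not in (
            "full_context",
            "sequential",
        ):
            raise SchemaError(
                f"response ({self.responder_id}, {self.question_id}): unknown "
                f"input_format {self.input_format!r}"
            )


@dataclass(frozen=True)
class QuestionMetrics:
    """Per-question ensemble summary over the model responders.

    ``mean_score`` is S_i, the mean of normalized per-model scores in [0, 1];
    ``sd_score`` its dispersion; ``n_incorrect`` counts models that failed to
    answer correctly; ``n_distinct_wrong`` counts distinct answers among the
    incorrect models; ``n_ambiguity_reports`` counts self-reported flags.
    """

    question_id: str
    mean_score: float
    sd_score: float
    n_incorrect: int
    n_distinct_wrong: int
    n_ambiguity_reports: int
    n_models: int

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise SchemaError("QuestionMetrics requires n_models >= 1")
        if not (0.0 <= self.mean_score <= 1.0 + 1e-12):
            raise SchemaError(f"mean_score {self.mean_score} outside [0, 1]")
        if self.sd_score < 0:
            raise SchemaError("sd_score must be nonnegative")
        if self.n_models == 1 and self.sd_score != 0:
            raise SchemaError("sd_score must be 0 with a single model")
        if not (0 <= self.n_incorrect <= self.n_models):
            raise SchemaError("n_incorrect outside [0, n_models]")
        if not (0 <= self.n_distinct_wrong <= self.n_incorrect):
            raise SchemaError("n_distinct_wrong outside [0, n_incorrect]")
        if not (0 <= self.n_ambiguity_reports <= self.n_models):
            raise SchemaError("n_ambiguity_reports outside [0, n_models]")


@dataclass(frozen=True)
class Thresholds:
    """Tagging, review, and pass thresholds.

    Defaults mirror the published detector: the low-performance tag fires
    when the ensemble mean is below 0.5 with SD below 0.3; the incoherence
    tag when SD exceeds 0.3; the ambiguity tag needs at least 2 wrong models
    with at least 2 distinct wrong answers; the subjective tag needs at least
    2 self-reports.  Components scoring below 15/20 are flagged for review;
    10/20 is the exam pass mark.
    """

    low_perf_mean: float = 0.5
    sd_split: float = 0.3
    min_wrong_models: int = 2
    min_distinct_wrong: int = 2
    min_ambiguity_reports: int = 2
    review_cutoff: float = 15.0
    pass_mark: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "low_perf_mean",
            "sd_split",
            "min_wrong_models",
            "min_distinct_wrong",
            "min_ambiguity_reports",
            "review_cutoff",
            "pass_mark",
        ):
            if not (getattr(self, name) > 0):
                raise SchemaError(f"threshold {name} must be positive")
        if self.min_distinct_wrong > self.min_wrong_models:
            raise SchemaError(
                "min_distinct_wrong cannot exceed min_wrong_models"
            )


@dataclass(frozen=True)
class QuestionBank:
    """A validated collection of questions and components."""

    questions: tuple[Question, ...]
    components: tuple[ComponentSpec, ...]

    def __post_init__(self) -> None:
        qids = [q.question_id for q in self.questions]
        if len(set(qids)) != len(qids):
            dupes = sorted({q for q in qids if qids.count(q) > 1})
            raise SchemaError(f"duplicate question ids: {dupes}")
        cids = [c.component_id for c in self.components]
        if len(set(cids)) != len(cids):
            raise SchemaError("duplicate component ids")
        known = set(qids)
        for comp in self.components:
            missing = [q for q in comp.question_ids if q not in known]
            if missing:
                raise SchemaError(
                    f"component {comp.component_id} references unknown "
                    f"questions {missing}"
                )

    def question(self, question_id: str) -> Question:
        try:
            return self.by_id[question_id]
        except KeyError:
            raise KeyError(f"unknown question id {question_id!r}") from None

    @property
    def by_id(self) -> Mapping[str, Question]:
        return {q.question_id: q for q in self.questions}


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

_QUESTION_COLS = ["question_id", "component_id", "format", "options", "key", "max_points"]
_COMPONENT_COLS = [
    "component_id",
    "dtype",
    "question_ids",
    "author_specialty",
    "author_rank",
    "cohort_label",
]
_RESPONSE_COLS = [
    "responder_id",
    "responder_kind",
    "question_id",
    "selected",
    "graded_points",
    "answer_text",
    "ambiguity_report",
    "input_format",
]


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    return df

def _opt(cell: str) -> str | None:
    cell = str(cell).strip()
    return cell or None


def _question_from_row(row: Mapping[str, object], where: str) -> Question:
    try:
        return Question(
            question_id=_clean_token(row["question_id"]),
            component_id=_clean_token(row["component_id"]),
            format=QuestionFormat(str(row["format"]).strip()),
            options=tuple(
                _clean_token(t)
                for t in str(row.get("options", "")).split(SEP)
                if t.strip()
            ),
            key=_parse_multi(row.get("key", "")),
            max_points=float(row.get("max_points") or 1.0),
        )
    except (ValueError, KeyError) as exc:
        raise SchemaError(f"{where}: {exc}") from exc


def _component_from_row(row: Mapping[str, object], where: str) -> ComponentSpec:
    try:
        return ComponentSpec(
            component_id=_clean_token(row["component_id"]),
            dtype=ComponentType(str(row["dtype"]).strip()),
            question_ids=tuple(
                _clean_token(t)
                for t in str(row["question_ids"]).split(SEP)
                if t.strip()
            ),
            author_specialty=_opt(row.get("author_specialty", "")),
            author_rank=_opt(row.get("author_rank", "")),
            cohort_label=_opt(row.get("cohort_label", "")),
        )
    except (ValueError, KeyError) as exc:
        raise SchemaError(f"{where}: {exc}") from exc


_TRUE = {"1", "true", "yes"}
_FALSE = {"", "0", "false", "no"}


def _parse_bool(cell: object, where: str) -> bool:
    text = str(cell).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise SchemaError(f"{where}: cannot parse boolean {cell!r}")


def read_question_bank(
    path: str | Path,
    components_path: str | Path | None = None,
    schema_dialect: str = "auto",
) -> QuestionBank:
    """Read a validated question bank.

    ``csv`` dialect: ``path`` is the questions table and ``components_path``
    the components table.  ``json`` dialect: ``path`` is a single bundle with
    ``questions`` and ``components`` arrays.  ``auto`` picks by extension.
    """
    path = Path(path)
    if schema_dialect == "auto":
        schema_dialect = "json" if path.suffix.lower() == ".json" else "csv"
    if schema_dialect == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        questions = tuple(
            _question_from_row(row, f"{path.name} questions[{i}]")
            for i, row in enumerate(payload.get("questions", []))
        )
        components = tuple(
            _component_from_row(row, f"{path.name} components[{i}]")
            for i, row in enumerate(payload.get("components", []))
        )
        return QuestionBank(questions, components)
    if schema_dialect != "csv":
        raise ValueError(f"unknown schema dialect {schema_dialect!r}")
    if components_path is None:
        raise ValueError("csv dialect requires a components_path")
    qdf = _read_table(path, _QUESTION_COLS[:5])
    cdf = _read_table(components_path, _COMPONENT_COLS[:3])
    questions = tuple(
        _question_from_row(row, f"{Path(path).name} row {i + 2}")
        for i, row in qdf.iterrows()
    )
    components = tuple(
        _component_from_row(row, f"{Path(components_path).name} row {i + 2}")
        for i, row in cdf.iterrows()
    )
    return QuestionBank(questions, components)


def write_question_bank(
    bank: QuestionBank,
    path: str | Path,
    components_path: str | Path | None = None,
    schema_dialect: str = "auto",
) -> None:
    """Serialize a bank in the same dialects accepted by the reader."""
    path = Path(path)
    if schema_dialect == "auto":
        schema_dialect = "json" if path.suffix.lower() == ".json" else "csv"
    qrows = [
        {
            "question_id": q.question_id,
            "component_id": q.component_id,
            "format": q.format.value,
            "options": SEP.join(q.options),
            "key": _fmt_multi(q.key),
            "max_points": q.max_points,
        }
        for q in bank.questions
    ]
    crows = [
        {
            "component_id": c.component_id,
            "dtype": c.dtype.value,
            "question_ids": SEP.join(c.question_ids),
            "author_specialty": c.author_specialty or "",
            "author_rank": c.author_rank or "",
            "cohort_label": c.cohort_label or "",
        }
        for c in bank.components
    ]
    if schema_dialect == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"questions": qrows, "components": crows}, fh, indent=1)
        return
    if components_path is None:
        raise ValueError("csv dialect requires a components_path")
    pd.DataFrame(qrows, columns=_QUESTION_COLS).to_csv(path, index=False)
    pd.DataFrame(crows, columns=_COMPONENT_COLS).to_csv(components_path, index=False)


def read_responses(path: str | Path) -> tuple[ResponseRecord, ...]:
    """Read response records from CSV, validating every row."""
    df = _read_table(path, _RESPONSE_COLS[:3])
    records = []
    for i, row in df.iterrows():
        where = f"{Path(path).name} row {i + 2}"
        selected_cell = str(row.get("selected", "")).strip()
        points_cell = str(row.get("graded_points", "")).strip()
        kind = str(row["responder_kind"]).strip()
        try:
            records.append(
                ResponseRecord(
                    responder_id=_clean_token(row["responder_id"]),
                    responder_kind=ResponderKind(kind),
                    question_id=_clean_token(row["question_id"]),
                    # empty selected cell on an MCQ row is a valid abstention:
                    # the row is MCQ-shaped whenever graded_points is absent
                    selected=None if points_cell else _parse_multi(selected_cell),
                    graded_points=float(points_cell) if points_cell else None,
                    answer_text=_opt(row.get("answer_text", "")),
                    ambiguity_report=_parse_bool(row.get("ambiguity_report", ""), where),
                    input_format=_opt(row.get("input_format", "")),
                )
            )
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"{where}: {exc}") from exc
    return tuple(records)


def write_responses(records: Iterable[ResponseRecord], path: str | Path) -> None:
    rows = [
        {
            "responder_id": r.responder_id,
            "responder_kind": r.responder_kind.value,
            "question_id": r.question_id,
            "selected": _fmt_multi(r.selected) if r.selected is not None else "",
            "graded_points": "" if r.graded_points is None else r.graded_points,
            "answer_text": r.answer_text or "",
            "ambiguity_report": int(r.ambiguity_report),
            "input_format": r.input_format or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_RESPONSE_COLS).to_csv(path, index=False)


def write_report(results: Sequence, path: str | Path, format: str = "json") -> None:
    """Write a component-quality report as json, csv, or markdown.

    ``results`` is a sequence of :class:`examaudit.quality.ComponentQuality`.
    json and csv round-trip losslessly at full float precision; markdown is a
    human-readable table with band labels and review flags.
    """
    path = Path(path)
    rows = [r.as_dict() for r in results]
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=1)
    elif format == "csv":
        flat = []
        for r in rows:
            flat.append(
                {
                    "component_id": r["component_id"],
                    "component_score": repr(r["component_score"]),
                    "band": r["band"],
                    "needs_review": int(r["needs_review"]),
                    "question_ids": SEP.join(r["question_ids"]),
                    "question_quality": SEP.join(repr(v) for v in r["question_quality"]),
                    "weights": SEP.join(repr(v) for v in r["weights"]),
                }
            )
        pd.DataFrame(flat).to_csv(path, index=False)
    elif format == "markdown":
        lines = [
            "| component | score /20 | band | needs review |",
            "|---|---|---|---|",
        ]
        for r in rows:
            lines.append(
                f"| {r['component_id']} | {r['component_score']:.2f} | "
                f"{r['band']} | {'yes' if r['needs_review'] else 'no'} |"
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {format!r}")


def merge_duplicate_responses(
    records: Sequence[ResponseRecord],
    input_format: str | None = None,
) -> tuple[ResponseRecord, ...]:
    """Collapse duplicate (responder, question) records.

    Identical duplicates collapse to one record; conflicting duplicates raise.
    ``input_format`` optionally restricts scoring to one presentation format
    before merging.
    """
    if input_format is not None:
        records = [r for r in records if r.input_format in (None, input_format)]
    seen: dict[tuple[str, str], ResponseRecord] = {}
    for rec in records:
        key = (rec.responder_id, rec.question_id)
        prev = seen.get(key)
        if prev is None:
            seen[key] = rec
        elif (prev.selected, prev.graded_points, prev.ambiguity_report) != (
            rec.selected,
            rec.graded_points,
            rec.ambiguity_report,
        ):
            raise SchemaError(
                f"conflicting duplicate responses for responder "
                f"{rec.responder_id!r}, question {rec.question_id!r}"
            )
    return tuple(seen.values())
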