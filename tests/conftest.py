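import pytest

from examaudit.model import (
    ComponentSpec,
    ComponentType,
    Question,
    QuestionBank,
    QuestionFormat,
    ResponderKind,
    ResponseRecord,
)

OPTIONS = ("A", "B", "C", "D", "E")


def mcq(qid="q1", key=("A", "C"), component="IQS1", max_points=1.0, fmt=QuestionFormat.MCQ):
    return Question(
        question_id=qid,
        component_id=component,
        format=fmt,
        options=OPTIONS,
        key=frozenset(key),
        max_points=max_points,
    )


def model_answer(responder, qid="q1", selected=(), report=False):
    return ResponseRecord(
        responder_id=responder,
        responder_kind=ResponderKind.model,
        question_id=qid,
        selected=frozenset(selected),
        ambiguity_report=report,
    )


def student_answer(responder, qid="q1", selected=()):
    return ResponseRecord(
        responder_id=responder,
        responder_kind=ResponderKind.student,
        question_id=qid,
        selected=frozenset(selected),
    )


@pytest.fixture
def question():
    """5-option multi-select item with key {A, C}."""
    return mcq()


@pytest.fixture
def small_bank():
    """One IQS component of three MCQ items plus one SAQ component."""
    questions = (
        mcq("q1", ("A", "C")),
        mcq("q2", ("B",), fmt=QuestionFormat.SBA),
        mcq("q3", ("A", "B", "D")),
        Question(
            question_id="q4",
            component_id="KFP1",
            format=QuestionFormat.SAQ,
            options=(),
            key=frozenset(),
            max_points=2.0,
        ),
    )
    components = (
        ComponentSpec(
            component_id="IQS1",
            dtype=ComponentType.IQS,
            question_ids=("q1", "q2", "q3"),
            author_specialty="intensivist",
            author_rank="clinical_fellow",
        ),
        ComponentSpec(
            component_id="KFP1",
            dtype=ComponentType.KFP,
            question_ids=("q4",),
            author_specialty="emergency",
            author_rank="full_professor",
        ),
    )
    return QuestionBank(questions, components)
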