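"""Grade a handful of answers against an answer key with partial credit.

A 5-option multi-select item with key {A, C} is graded for four responders.
One discrepancy (a missed key option or a wrongly ticked distractor) earns
half the item's points, two earn a fifth, and anything worse earns nothing.
"""

from examaudit import (
    Question,
    QuestionFormat,
    ResponderKind,
    ResponseRecord,
    grade_response,
)

question = Question(
    question_id="q1",
    component_id="IQS1",
    format=QuestionFormat.MCQ,
    options=("A", "B", "C", "D", "E"),
    key=frozenset({"A", "C"}),
    max_points=1.0,
)

answers = {
    "perfect": {"A", "C"},
    "one_omission": {"A"},
    "omission_plus_distractor": {"A", "B"},
    "abstention": set(),
    "everything_ticked": {"A", "B", "C", "D", "E"},
}

print(f"key = {sorted(question.key)}, options = {question.options}")
for name, selected in answers.items():
    record = ResponseRecord(
        responder_id=name,
        responder_kind=ResponderKind.student,
        question_id="q1",
        selected=frozenset(selected),
    )
    g = grade_response(question, record)
    print(
        f"{name:25s} selected={sorted(selected) or '[]'}  "
        f"discrepancies={g.discrepancies}  points={g.points:.2f}"
    )

# The discrepancy count is the symmetric difference with the key, so an
# abstention costs the whole key (here 2 discrepancies -> 0.2 points).
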