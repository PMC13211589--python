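"""Schema validation and tabular round-trips for banks and responses."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from examaudit.model import (
    ComponentSpec,
    ComponentType,
    Question,
    QuestionBank,
    QuestionFormat,
    QuestionMetrics,
    ResponderKind,
    ResponseRecord,
    SchemaError,
    Thresholds,
    merge_duplicate_responses,
    read_question_bank,
    read_responses,
    write_question_bank,
    write_responses,
)

from conftest import model_answer, student_answer


class TestQuestionInvariants:
    def test_key_outside_options_rejected(self):
        with pytest.raises(SchemaError, match="key labels"):
            Question("q1", "c1", QuestionFormat.MCQ, ("A", "B"), frozenset({"F"}))

    def test_sba_needs_single_key(self):
        with pytest.raises(SchemaError, match="SBA"):
            Question("q1", "c1", QuestionFormat.SBA, ("A", "B", "C"), frozenset("AB"))

    def test_saq_carries_no_options(self):
        with pytest.raises(SchemaError, match="SAQ"):
            Question("q1", "c1", QuestionFormat.SAQ, ("A", "B"), frozenset())

    def test_mcq_needs_two_options(self):
        with pytest.raises(SchemaError, match=">=2 options"):
            Question("q1", "c1", QuestionFormat.MCQ, ("A",), frozenset({"A"}))

    def test_whitespace_stripped_but_case_kept(self):
        q = Question("q1", "c1", QuestionFormat.MCQ, (" a ", "A"), frozenset({"a"}))
        assert q.options == ("a", "A")
        assert q.key == frozenset({"a"})


class TestResponseInvariants:
    def test_student_cannot_self_report(self):
        with pytest.raises(SchemaError, match="ambiguity self-report"):
            ResponseRecord(
                "s1", ResponderKind.student, "q1",
                selected=frozenset({"A"}), ambiguity_report=True,
            )

    def test_exactly_one_payload(self):
        with pytest.raises(SchemaError, match="exactly one"):
            ResponseRecord(
                "s1", ResponderKind.student, "q1",
                selected=frozenset({"A"}), graded_points=1.0,
            )
        with pytest.raises(SchemaError, match="exactly one"):
            ResponseRecord("s1", ResponderKind.student, "q1")

    def test_empty_selection_is_a_valid_abstention(self):
        rec = ResponseRecord(
            "s1", ResponderKind.student, "q1", selected=frozenset()
        )
        assert rec.selected == frozenset()


class TestMetricsInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_incorrect=5),  # > n_models
            dict(n_distinct_wrong=3),  # > n_incorrect
            dict(mean_score=1.2),
            dict(sd_score=-0.1),
            dict(n_models=1, sd_score=0.2),  # single model forces sd 0
        ],
    )
    def test_invalid_metrics_rejected(self, kwargs):
        base = dict(
            question_id="q1", mean_score=0.5, sd_score=0.1,
            n_incorrect=2, n_distinct_wrong=2, n_ambiguity_reports=0, n_models=4,
        )
        with pytest.raises(SchemaError):
            QuestionMetrics(**{**base, **kwargs})

    def test_thresholds_reject_inconsistent_minimums(self):
        with pytest.raises(SchemaError):
            Thresholds(min_wrong_models=1, min_distinct_wrong=2)


class TestBankIO:
    def test_csv_round_trip(self, small_bank, tmp_path):
        qp, cp = tmp_path / "q.csv", tmp_path / "c.csv"
        write_question_bank(small_bank, qp, cp)
        assert read_question_bank(qp, cp) == small_bank

    def test_json_round_trip(self, small_bank, tmp_path):
        path = tmp_path / "bank.json"
        write_question_bank(small_bank, path)
        assert read_question_bank(path) == small_bank

    def test_schema_error_names_offending_row(self, tmp_path):
        qp = tmp_path / "q.csv"
        qp.write_text(
            "question_id,component_id,format,options,key\n"
            "q1,c1,MCQ,A|B|C|D|E,F\n"
        )
        cp = tmp_path / "c.csv"
        cp.write_text("component_id,dtype,question_ids\nc1,IQS,q1\n")
        with pytest.raises(SchemaError, match="row 2"):
            read_question_bank(qp, cp)

    def test_missing_column_rejected(self, tmp_path):
        qp = tmp_path / "q.csv"
        qp.write_text("question_id,component_id\nq1,c1\n")
        with pytest.raises(SchemaError, match="missing required columns"):
            read_question_bank(qp, tmp_path / "c.csv")

    def test_component_referencing_unknown_question_rejected(self):
        q = Question("q1", "c1", QuestionFormat.MCQ, ("A", "B"), frozenset({"A"}))
        c = ComponentSpec("c1", ComponentType.IQS, ("q1", "q9"))
        with pytest.raises(SchemaError, match="q9"):
            QuestionBank((q,), (c,))


class TestResponseIO:
    def test_model_record_with_report(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "responder_id,responder_kind,question_id,selected,graded_points,"
            "answer_text,ambiguity_report,input_format\n"
            "gptX,model,q1,A|C,,,1,full_context\n"
        )
        (rec,) = read_responses(path)
        assert rec.selected == frozenset({"A", "C"})
        assert rec.ambiguity_report is True

    def test_student_ambiguity_flag_rejected(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "responder_id,responder_kind,question_id,selected,graded_points,"
            "answer_text,ambiguity_report,input_format\n"
            "s1,student,q1,A,,,true,\n"
        )
        with pytest.raises(SchemaError, match="row 2"):
            read_responses(path)

    def test_empty_selected_reads_as_abstention(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "responder_id,responder_kind,question_id,selected,graded_points,"
            "answer_text,ambiguity_report,input_format\n"
            "s1,student,q1,,,,,\n"
        )
        (rec,) = read_responses(path)
        assert rec.selected == frozenset()
        assert rec.graded_points is None

    def test_round_trip(self, tmp_path):
        records = (
            model_answer("m1", "q1", {"A", "C"}, report=True),
            student_answer("s1", "q1", set()),
            ResponseRecord(
                "s2", ResponderKind.student, "q4",
                graded_points=1.5, answer_text="shock index",
            ),
        )
        path = tmp_path / "r.csv"
        write_responses(records, path)
        assert set(read_responses(path)) == set(records)


class TestMergeDuplicates:
    def test_identical_duplicates_collapse(self):
        a = model_answer("m1", "q1", {"A"})
        merged = merge_duplicate_responses([a, a])
        assert merged == (a,)

    def test_conflicting_duplicates_raise(self):
        with pytest.raises(SchemaError, match="conflicting"):
            merge_duplicate_responses(
                [model_answer("m1", "q1", {"A"}), model_answer("m1", "q1", {"B"})]
            )

    def test_input_format_restriction(self):
        full = ResponseRecord(
            "m1", ResponderKind.model, "q1",
            selected=frozenset({"A"}), input_format="full_context",
        )
        seq = ResponseRecord(
            "m1", ResponderKind.model, "q1",
            selected=frozenset({"B"}), input_format="sequential",
        )
        merged = merge_duplicate_responses([full, seq], input_format="sequential")
        assert merged == (seq,)


# randomized corruption property: every schema violation constructed from a
# valid record is rejected
_CORRUPTIONS = [
    lambda d: {**d, "mean_score": 1.5},
    lambda d: {**d, "sd_score": -0.2},
    lambda d: {**d, "n_incorrect": d["n_models"] + 1},
    lambda d: {**d, "n_distinct_wrong": d["n_incorrect"] + 1},
    lambda d: {**d, "n_ambiguity_reports": d["n_models"] + 2},
]


@given(
    data=st.fixed_dictionaries(
        {
            "mean_score": st.floats(0, 1),
            "sd_score": st.floats(0, 0.6),
            "n_models": st.integers(2, 6),
        }
    ),
    corruption=st.sampled_from(_CORRUPTIONS),
    n_wrong=st.integers(0, 2),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_randomized_corruptions_rejected(data, corruption, n_wrong):
    base = dict(
        question_id="q1",
        mean_score=data["mean_score"],
        sd_score=data["sd_score"],
        n_incorrect=min(n_wrong, data["n_models"]),
        n_distinct_wrong=min(n_wrong, data["n_models"]),
        n_ambiguity_reports=0,
        n_models=data["n_models"],
    )
    QuestionMetrics(**base)  # the uncorrupted record is valid
    with pytest.raises(SchemaError):
        QuestionMetrics(**corruption(base))
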