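"""Diagnostic tags, composite ambiguity score, and combination reporting."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from examaudit.model import QuestionMetrics, Thresholds
from examaudit.tagging import (
    TAG_NAMES,
    TagVector,
    UnreachableScoreError,
    assign_tags,
    round_half_up,
    score_label,
    tag_combinations,
)


def metrics(mean=1.0, sd=0.0, wrong=0, distinct=None, reports=0, n=4, qid="q1"):
    if distinct is None:
        distinct = wrong
    return QuestionMetrics(
        question_id=qid,
        mean_score=mean,
        sd_score=sd,
        n_incorrect=wrong,
        n_distinct_wrong=distinct,
        n_ambiguity_reports=reports,
        n_models=n,
    )


def oracle(m: QuestionMetrics) -> tuple[int, int, int, int]:
    """Independent literal transcription of the four tag criteria."""
    ambiguity = 1 if (m.n_incorrect >= 2 and m.n_distinct_wrong >= 2) else 0
    low_perf = 1 if (m.mean_score < 0.5 and m.sd_score < 0.3) else 0
    incoherence = 1 if m.sd_score > 0.3 else 0
    subjective = 1 if m.n_ambiguity_reports >= 2 else 0
    return (ambiguity, low_perf, incoherence, subjective)


class TestAssignTags:
    def test_flawless_item(self):
        t = assign_tags(metrics())
        assert t.tags == frozenset()
        assert t.ambiguity_score == 0

    def test_shared_misconception_is_low_performance_not_ambiguity(self):
        t = assign_tags(metrics(mean=0.30, sd=0.10, wrong=4, distinct=1))
        assert t.low_performance == 1
        assert t.ambiguity == 0
        assert t.incoherence == 0
        assert t.ambiguity_score == 1

    def test_maximal_feasible_score(self):
        t = assign_tags(metrics(mean=0.40, sd=0.45, wrong=3, distinct=2, reports=2))
        assert (t.ambiguity, t.incoherence, t.subjective_ambiguity) == (1, 1, 1)
        assert t.low_performance == 0
        assert t.ambiguity_score == 3

    def test_sd_boundary_fires_neither_sd_tag(self):
        """At SD exactly 0.3 the strict inequalities leave both tags off."""
        t = assign_tags(metrics(mean=0.40, sd=0.30, wrong=1, distinct=1))
        assert t.low_performance == 0
        assert t.incoherence == 0

    def test_custom_thresholds(self):
        lax = Thresholds(min_ambiguity_reports=1)
        t = assign_tags(metrics(reports=1), lax)
        assert t.subjective_ambiguity == 1

    @given(
        mean=st.floats(0, 1),
        sd=st.floats(0, 0.6),
        wrong=st.integers(0, 4),
        distinct_frac=st.floats(0, 1),
        reports=st.integers(0, 4),
    )
    @settings(max_examples=1000, deadline=None, derandomize=True)
    def test_oracle_equivalence(self, mean, sd, wrong, distinct_frac, reports):
        """assign_tags matches the independent criteria transcription."""
        distinct = round(distinct_frac * wrong)
        m = metrics(mean=mean, sd=sd if wrong else sd, wrong=wrong,
                    distinct=distinct, reports=reports)
        t = assign_tags(m)
        assert (t.ambiguity, t.low_performance, t.incoherence,
                t.subjective_ambiguity) == oracle(m)
        assert t.ambiguity_score == sum(oracle(m))

    @given(
        mean=st.floats(0, 1),
        sd=st.floats(0, 0.6),
        wrong=st.integers(0, 4),
        reports=st.integers(0, 3),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_exclusivity_and_report_monotonicity(self, mean, sd, wrong, reports):
        m = metrics(mean=mean, sd=sd, wrong=wrong, reports=reports)
        t = assign_tags(m)
        assert t.low_performance + t.incoherence <= 1
        assert t.ambiguity_score <= 3
        bumped = assign_tags(metrics(mean=mean, sd=sd, wrong=wrong, reports=reports + 1))
        assert bumped.ambiguity_score >= t.ambiguity_score


class TestTagVectorInvariants:
    def test_mutual_exclusivity_enforced(self):
        with pytest.raises(ValueError, match="mutually exclusive"):
            TagVector("q1", 0, 1, 1, 0, 2)

    def test_score_must_match_sum(self):
        with pytest.raises(ValueError, match="sum"):
            TagVector("q1", 1, 0, 0, 0, 2)

    def test_max_score_over_exclusive_configurations_is_3(self):
        """Enumerating all 16 tag vectors under the SD exclusivity rule."""
        feasible = [
            bits
            for bits in itertools.product([0, 1], repeat=4)
            if bits[1] + bits[2] <= 1  # low_performance, incoherence
        ]
        assert max(sum(bits) for bits in feasible) == 3
        for bits in feasible:
            TagVector("q1", *bits, ambiguity_score=sum(bits))  # all constructible


class TestScoreLabel:
    @pytest.mark.parametrize(
        "score, label",
        [
            (0, "No issues detected"),
            (1, "Minor concern"),
            (2, "Moderate ambiguity"),
            (3, "Strong signal of item flaw or misleading structure"),
        ],
    )
    def test_labels(self, score, label):
        assert score_label(score) == label

    def test_unreachable_score_trips(self):
        with pytest.raises(UnreachableScoreError):
            score_label(4)


def make_tags(combos):
    out = []
    for i, combo in enumerate(combos):
        bits = {name: int(name in combo) for name in TAG_NAMES}
        out.append(TagVector(f"q{i}", **bits, ambiguity_score=sum(bits.values())))
    return out


class TestTagCombinations:
    def test_printed_shares_over_264_items(self):
        combos = (
            [("ambiguity", "incoherence")] * 78
            + [("low_performance", "ambiguity")] * 52
            + [("ambiguity",)] * 36
            + [("ambiguity", "incoherence", "subjective_ambiguity")] * 5
            + [()] * 93
        )
        table = tag_combinations(make_tags(combos))
        share = dict(zip(table.combination, table.percent))
        assert share["ambiguity+incoherence"] == 29.5
        assert share["ambiguity+low_performance"] == 19.7
        assert share["ambiguity"] == 13.6
        assert share["ambiguity+incoherence+subjective_ambiguity"] == 1.9

    def test_empty_input_gives_empty_table(self):
        assert len(tag_combinations([])) == 0

    @given(
        counts=st.lists(st.integers(1, 40), min_size=1, max_size=6),
        seed=st.integers(0, 50),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_shares_sum_to_100(self, counts, seed):
        import random

        rng = random.Random(seed)
        pool = [(), ("ambiguity",), ("incoherence",), ("ambiguity", "incoherence"),
                ("subjective_ambiguity",), ("low_performance", "ambiguity")]
        combos = []
        for c in counts:
            combos += [rng.choice(pool)] * c
        table = tag_combinations(make_tags(combos))
        assert table["count"].sum() == len(combos)
        assert table["percent"].sum() == pytest.approx(100.0, abs=0.1 * len(table))


def test_round_half_up_ties_go_up():
    assert round_half_up(0.25, 1) == 0.3
    assert round_half_up(29.45, 1) == 29.5
    assert round_half_up(2.5, 0) == 3.0
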