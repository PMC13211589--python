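"""Synthetic exams with planted ambiguity.

The generator emulates the study design end-to-end with no external data: a
question bank split into docimological components, a student cohort, and a
small model ensemble.  Ambiguity is planted as *multiple plausible answer
keys*: an ambiguous item carries the official key plus K-1 alternative
readings, each obtained by swapping one key option for one distractor.  On
such items each model independently follows one reading and then answers
that reading's key with its per-option competence; models also self-report
ambiguity with different probabilities on ambiguous versus clean items.

Students follow a one-parameter logistic response model: each option is
handled correctly with probability ``logistic(ability - difficulty)``, with
extra toggle noise on ambiguous items.

Seeding: a single root seed derives independent per-question and
per-responder substreams, so regenerating any slice of the data is stable.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    ComponentSpec,
    ComponentType,
    Question,
    QuestionBank,
    QuestionFormat,
    ResponderKind,
    ResponseRecord,
)

__all__ = [
    "SimulationConfig",
    "GroundTruthItem",
    "GroundTruth",
    "generate_bank",
    "simulate_students",
    "simulate_models",
    "simulate_exam",
]

# substream tags for the root SeedSequence
_BANK, _STUDENT, _MODEL, _ABILITY = 0, 1, 2, 3


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic exam.

    Defaults follow the emulated study: 4 models, 5-option multi-select
    items, and a strong planted-ambiguity effect (K = 2 plausible keys, a
    model follows the alternative reading with probability 0.8, self-reports
    ambiguity with probability 0.6 on ambiguous items versus 0.05 on clean
    ones, and answers its chosen reading with per-option competence 0.95).
    """

    n_components: int = 5
    dtype_mix: tuple[str, ...] = ("IQS", "PCC", "mPCC", "KFP")
    questions_per_component: int = 8
    n_options: int = 5
    key_sizes: tuple[int, ...] = (1, 2, 3)
    n_students: int = 30
    n_models: int = 4
    student_ability_mean: float = 2.0
    student_ability_sd: float = 1.0
    difficulty_sd: float = 1.0
    student_ambiguity_noise: float = 0.15
    model_competence: tuple[float, ...] = (0.95, 0.95, 0.95, 0.95)
    ambiguity_prevalence: float = 0.3
    n_plausible_keys: int = 2  # K: official key + K-1 alternative readings
    follow_alternative: float = 0.8
    report_ambiguous: float = 0.6
    report_clean: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "student_ambiguity_noise",
            "ambiguity_prevalence",
            "follow_alternative",
            "report_ambiguous",
            "report_clean",
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be a probability")
        if any(not (0.0 <= c <= 1.0) for c in self.model_competence):
            raise ValueError("model competences must be probabilities")
        if len(self.model_competence) != self.n_models:
            raise ValueError("need one competence per model")
        if self.n_plausible_keys < 2:
            raise ValueError("K (plausible keys) must be at least 2")
        if self.n_options < 3 or self.n_options > 26:
            raise ValueError("n_options must be in [3, 26]")
        if max(self.key_sizes) >= self.n_options:
            raise ValueError("key sizes must leave at least one distractor")


@dataclass(frozen=True)
class GroundTruthItem:
    question_id: str
    is_ambiguous: bool
    alternative_keys: tuple[frozenset[str], ...]  # empty for clean items
    difficulty: float


@dataclass(frozen=True)
class GroundTruth:
    items: tuple[GroundTruthItem, ...]

    def __getitem__(self, question_id: str) -> GroundTruthItem:
        return self._by_id[question_id]

    @property
    def _by_id(self) -> dict[str, GroundTruthItem]:
        return {it.question_id: it for it in self.items}

    @property
    def ambiguous_ids(self) -> frozenset[str]:
        return frozenset(it.question_id for it in self.items if it.is_ambiguous)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "question_id": it.question_id,
                    "is_ambiguous": int(it.is_ambiguous),
                    "alternative_keys": ";".join(
                        "|".join(sorted(k)) for k in it.alternative_keys
                    ),
                    "difficulty": it.difficulty,
                }
                for it in self.items
            ]
        )


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def _alternative_keys(
    official: frozenset[str],
    options: Sequence[str],
    k_minus_one: int,
    rng: np.random.Generator,
) -> tuple[frozenset[str], ...]:
    """Alternative readings: swap one key option for one distractor each."""
    distractors = [o for o in options if o not in official]
    alts: list[frozenset[str]] = []
    seen = {official}
    attempts = 0
    while len(alts) < k_minus_one and attempts < 100:
        attempts += 1
        drop = rng.choice(sorted(official))
        add = rng.choice(distractors)
        alt = (official - {drop}) | {add}
        if alt not in seen:
            seen.add(alt)
            alts.append(alt)
    if len(alts) < k_minus_one:
        raise ValueError("could not construct enough distinct alternative keys")
    return tuple(alts)


def generate_bank(config: SimulationConfig) -> tuple[QuestionBank, GroundTruth]:
    """Generate a validated bank plus its planted-ambiguity ground truth."""
    letters = string.ascii_uppercase[: config.n_options]
    questions: list[Question] = []
    components: list[ComponentSpec] = []
    truth: list[GroundTruthItem] = []
    specialties = ("intensivist", "emergency")
    ranks = ("clinical_fellow", "associate_professor", "full_professor")
    qi = 0
    for ci in range(config.n_components):
        dtype = ComponentType(config.dtype_mix[ci % len(config.dtype_mix)])
        cid = f"{dtype.value}{ci + 1}"
        qids = []
        for _ in range(config.questions_per_component):
            rng = _rng(config, _BANK, qi)
            qid = f"q{qi + 1:04d}"
            size = int(rng.choice(config.key_sizes))
            key = frozenset(rng.choice(list(letters), size=size, replace=False))
            ambiguous = bool(rng.random() < config.ambiguity_prevalence)
            alts = (
                _alternative_keys(key, letters, config.n_plausible_keys - 1, rng)
                if ambiguous
                else ()
            )
            questions.append(
                Question(
                    question_id=qid,
                    component_id=cid,
                    format=QuestionFormat.MCQ,
                    options=tuple(letters),
                    key=key,
                    max_points=1.0,
                )
            )
            truth.append(
                GroundTruthItem(
                    question_id=qid,
                    is_ambiguous=ambiguous,
                    alternative_keys=alts,
                    difficulty=float(rng.normal(0.0, config.difficulty_sd)),
                )
            )
            qids.append(qid)
            qi += 1
        components.append(
            ComponentSpec(
                component_id=cid,
                dtype=dtype,
                question_ids=tuple(qids),
                author_specialty=specialties[ci % 2],
                author_rank=ranks[ci % 3],
                cohort_label="synthetic",
            )
        )
    return QuestionBank(tuple(questions), tuple(components)), GroundTruth(tuple(truth))


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_students(
    bank: QuestionBank,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[ResponseRecord, ...]:
    """Simulate the student cohort's option selections."""
    records: list[ResponseRecord] = []
    for s in range(config.n_students):
        ability = float(
            _rng(config, _ABILITY, s).normal(
                config.student_ability_mean, config.student_ability_sd
            )
        )
        for qi, q in enumerate(bank.questions):
            item = truth[q.question_id]
            rng = _rng(config, _STUDENT, s, qi)
            p = _logistic(ability - item.difficulty)
            selected = set()
            for opt in q.options:
                ok = rng.random() < p
                if item.is_ambiguous and rng.random() < config.student_ambiguity_noise:
                    ok = not ok
                if (opt in q.key) == ok:
                    selected.add(opt)
            records.append(
                ResponseRecord(
                    responder_id=f"student_{s + 1:03d}",
                    responder_kind=ResponderKind.student,
                    question_id=q.question_id,
                    selected=frozenset(selected),
                )
            )
    return tuple(records)


def simulate_models(
    bank: QuestionBank,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[ResponseRecord, ...]:
    """Simulate the model ensemble's answers and ambiguity self-reports.

    On clean items a model reproduces the official key with its per-option
    competence.  On ambiguous items it first picks a reading — the official
    key, or with probability ``follow_alternative`` one of the alternatives —
    and then answers that reading's key with the same competence.
    """
    records: list[ResponseRecord] = []
    for m in range(config.n_models):
        competence = config.model_competence[m]
        for qi, q in enumerate(bank.questions):
            item = truth[q.question_id]
            rng = _rng(config, _MODEL, m, qi)
            reading = q.key
            if item.is_ambiguous and rng.random() < config.follow_alternative:
                reading = item.alternative_keys[
                    int(rng.integers(len(item.alternative_keys)))
                ]
            selected = set()
            for opt in q.options:
                desired = opt in reading
                if rng.random() >= competence:
                    desired = not desired
                if desired:
                    selected.add(opt)
            p_report = (
                config.report_ambiguous if item.is_ambiguous else config.report_clean
            )
            records.append(
                ResponseRecord(
                    responder_id=f"model_{m + 1}",
                    responder_kind=ResponderKind.model,
                    question_id=q.question_id,
                    selected=frozenset(selected),
                    ambiguity_report=bool(rng.random() < p_report),
                    input_format="full_context",
                )
            )
    return tuple(records)


def simulate_exam(
    config: SimulationConfig,
) -> tuple[QuestionBank, GroundTruth, tuple[ResponseRecord, ...], tuple[ResponseRecord, ...]]:
    """Generate bank, ground truth, student responses, and model responses."""
    bank, truth = generate_bank(config)
    students = simulate_students(bank, truth, config)
    models = simulate_models(bank, truth, config)
    return bank, truth, students, models
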