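# examaudit

**A-priori ambiguity and quality auditing of exam items from
model-ensemble disagreement.**

Most quality control of academic exams happens *after* the exam: items that
confused everyone are struck from the scoring, at real cost in time, budget
and student trust. `examaudit` implements the opposite workflow — screen an
exam *before* it is administered by letting an ensemble of language models
(or any set of expert responders) sit it, and flag the items on which the
ensemble disagrees, fails uniformly, or self-reports ambiguity. It was
designed for medical-school docimology (progressive clinical cases,
key-feature problems, isolated question sequences built from multi-select
MCQs and short-answer questions) but applies to any keyed exam.

## The method

**Partial-credit grading.** A response to a multi-select item is scored by
its *discrepancies* — the symmetric difference between the selected option
set and the answer key (a wrongly ticked distractor or an omitted correct
option each count one). With 0 / 1 / 2 / >2 discrepancies a response earns
1 / 0.5 / 0.2 / 0 of the item's points. Exam totals are normalized to a
20-point scale (pass mark 10).

**Ensemble metrics.** Each item is answered by *n* model responders
(4 by default). Per item the package computes the mean normalized score
S_i, its SD, the number of models answering incorrectly, the number of
*distinct* wrong answers, and the number of models self-reporting
ambiguity.

**Four diagnostic tags**, summed into a composite ambiguity score
A_i ∈ {0, …, 3}:

| tag | fires when |
|---|---|
| ambiguity | ≥ 2 models wrong **and** ≥ 2 distinct wrong answers |
| low performance | mean S_i < 0.5 **and** SD < 0.3 |
| incoherence | SD > 0.3 |
| subjective ambiguity | ≥ 2 models self-report ambiguity |

Low performance and incoherence depend on opposing SD thresholds and are
mutually exclusive, so A_i never exceeds 3 (0 "No issues detected" …
3 "Strong signal of item flaw or misleading structure"). An elbow-point
(knee) detector on each metric's sorted distribution supports data-driven
threshold checks.

**Component quality.** Per item Q_i = 20 × S_i; per component
`score = Σ Q_i w_i / Σ w_i` with w_i = 1/(1 + A_i), so ambiguous items are
down-weighted. Scores are banded — [18, 20] excellent, [15, 18) very good,
[12, 15) moderate, [10, 12) poor, [0, 10) insufficient — and components
below 15/20 are flagged for author re-review.

**Cohort statistics.** Model-vs-student (or any two-group) comparisons use
a Shapiro-Wilk-gated choice between a two-tailed Student t test and a
two-sided Mann-Whitney U test (exact for small untied groups).

**Synthetic validation.** Because no exam content ships with the package,
a simulator generates banks with *planted* ambiguity — items admitting a
second plausible answer key — plus a logistic-ability student cohort and a
model ensemble that scatters across the plausible readings and
self-reports probabilistically. Ground truth lets you measure how well the
tags recover the planted flaws.

## Worked example

```bash
python examples/audit_synthetic_exam.py
```

```
questions: 200, planted ambiguous: 68
flagged at score >= 2: 72
sensitivity = 1.000  (planted items recovered)
specificity = 0.970  (clean items left alone)

component quality (ambiguity-weighted, 20-point scale):
  IQS1     15.25  very_good  ok
  PCC2     15.86  very_good  ok
  mPCC3    14.87  moderate   REVIEW
  KFP4     14.01  moderate   REVIEW
  IQS5     14.83  moderate   REVIEW
  PCC6     15.81  very_good  ok
  ...
```

Every planted-ambiguous item was flagged at composite score ≥ 2 while 97%
of clean items were left alone; components dragged below 15/20 by flagged
items are marked for re-review. The other examples
(`grade_responses.py`, `compare_models_to_students.py`,
`data_driven_thresholds.py`) walk through grading, the gated two-sample
comparison, and elbow-based thresholds in the same style.

The same pipeline is available from the shell:

```bash
examaudit simulate --outdir fixtures/ --seed 0
examaudit run --questions fixtures/questions.csv \
              --components fixtures/components.csv \
              --responses fixtures/responses.csv \
              --out report.json
```

Subcommands `grade`, `metrics`, `tag`, `quality`, `compare` and `elbow`
expose the individual stages; every subcommand accepts `--config` with a
YAML file overriding thresholds, the rubric, or simulator settings.

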