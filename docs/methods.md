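# Methods

This note documents the models, conventions and numerical choices behind
`examaudit`, in the package's own terms.

## Grading model

A multi-select response is compared with the answer key by symmetric
difference: each wrongly selected distractor and each omitted key option
is one *discrepancy*. Both error directions are counted because a grader
cannot distinguish "ticked too much" from "ticked too little" in terms of
evidence of mastery; the symmetric difference is the only symmetric count
consistent with penalizing both. Consequences worth knowing:

* An abstention (empty selection) costs `|key|` discrepancies.
* A single-best-answer item answered with the wrong single option has 2
  discrepancies (one omission, one false positive) and earns the
  two-discrepancy fraction. Faculties that treat SBA as all-or-nothing can
  set `Rubric(sba_all_or_nothing=True)`.

The rubric fractions (1, 0.5, 0.2, 0 of `max_points` for 0, 1, 2, >2
discrepancies) are configurable so other faculties' rubrics can be
expressed; the defaults are the conventional ones. Fractions scale with
`max_points` — the alternative reading (absolute 0.5 points regardless of
item weight) would let normalized scores leave [0, 1].

Short-answer items cannot be auto-graded; they carry externally assigned
points that pass through unchanged.

Exam totals are `20 × Σpoints / Σmax_points`; the pass mark of 10/20 is
inclusive (a score of exactly 10 passes).

## Ensemble metrics

Per item, over the model responders only:

* `mean_score` (S_i) and `sd_score` of the normalized scores. The SD uses
  the sample estimator (n−1) by default — the natural choice when treating
  the 4 models as a sample of possible expert readers — with a population
  option for users who regard the ensemble as exhaustive. With a single
  model the SD is defined as 0.
* `n_incorrect`: models with normalized score strictly below 1 (any
  discrepancy). A laxer cutoff is available via `incorrect_cutoff`.
* `n_distinct_wrong`: distinct answers among the incorrect models — option
  sets compared by equality for MCQ-like items; whitespace/case-normalized
  answer text for SAQs, falling back to equality of graded points when no
  text was recorded. Deduplication matters: several models converging on
  the same wrong answer indicates a shared misconception, not ambiguity.
* `n_ambiguity_reports`: count of model self-reports.

Reductions run over score-sorted inputs so the results are exactly
invariant to responder order.

## Tags and the composite score

All four criteria use the comparisons as written in the table in the
README: strict `<`/`>` for the mean and SD cutoffs, `≥` for the
"at least 2" counts. At SD exactly equal to the split (0.3) neither
SD-based tag fires. Because low performance and incoherence are mutually
exclusive, the composite score's reachable maximum is 3; the engine
carries a tripwire (`UnreachableScoreError`) that aborts if a higher score
is ever constructed, rather than silently reporting it.

Thresholds (0.5 mean, 0.3 SD split, the three "at least 2" minimums, the
15/20 review cutoff, the 10/20 pass mark) live in one `Thresholds` object
and a YAML config block. The elbow detector is deliberately advisory: it
reports the knee of a sorted metric distribution (maximum perpendicular
distance to the chord after min-max normalization of both axes, no
smoothing since per-exam samples are small, ties broken toward the earlier
sorted index, `None` when the maximum distance is below a flatness
tolerance of 0.02 in normalized units), but the fixed defaults remain
canonical.

Tag-combination shares are rounded half-up to one decimal, the usual
reporting convention.

## Component quality

Q_i = 20·S_i; w_i = 1/(1+A_i); component score = Σ Q_i w_i / Σ w_i. The
published band intervals share endpoints; they are resolved half-open
`[lower, upper)` with the top band closed at 20. The boundary value 15
belongs to "very good" — consistent with the review rule, which flags only
components *strictly below* 15.

## Two-sample comparisons

The gate applies Shapiro-Wilk to each group separately at α = 0.05 and
uses the pooled-variance Student t test only when both pass; otherwise a
two-sided Mann-Whitney U. (Near-)constant groups are routed to the rank
test, where Shapiro-Wilk is undefined. Mann-Whitney uses the exact null
distribution when both groups have ≤ 8 untied observations, otherwise the
normal approximation with continuity and tie correction. Comparing a
4-member ensemble against a cohort is fragile; the package warns below
n = 5 per group but still computes, since that comparison is part of the
intended workflow.

No multiple-testing correction is applied across comparisons; users
running many groupings should correct downstream.

## Synthetic exams

The simulator emulates the study design, not real model behavior; its
purpose is to make every downstream rule exercisable against known ground
truth.

* **Planted ambiguity** is identified with *multiple plausible answer
  keys*: with prevalence π (default 0.3) an item carries K − 1 alternative
  readings (K = 2 by default), each formed by swapping one key option for
  one distractor — a competing reading two discrepancies from the official
  key.
* **Models**: per item, a model follows an alternative reading with
  probability 0.8 (default), then reproduces its chosen reading's key with
  per-option competence 0.95; it self-reports ambiguity with probability
  0.6 on ambiguous items and 0.05 on clean ones. These defaults constitute
  the strong-effect validation condition used by the acceptance tests
  (200 questions, 4 models).
* **Students**: one latent ability per student (normal on the logit scale,
  mean 2.0, SD 1.0) against one latent difficulty per item (normal,
  SD 1.0); each option is handled correctly with probability
  `logistic(ability − difficulty)`, with extra toggle noise (0.15) on
  ambiguous items. The ability default was calibrated once so the cohort
  mean lands near 12/20 (SD ≈ 3) — the range typical of real cohorts on a
  20-point scale — and is independent of the detection criteria, which use
  model responses only.
* **Seeding**: every random draw comes from a substream keyed by
  (root seed, stage, responder index, question index), so a fixed seed
  yields byte-identical output and any slice can be regenerated without
  the rest.

What the simulator does **not** model: correlated errors between models
sharing training data, within-case learning across sequenced questions,
distractor-specific attractiveness, or free-text answers (synthetic items
are all multi-select). Passing the planted-flaw recovery tests therefore
shows the detector's rules are implemented and discriminating under the
stated generative assumptions — not that real exams will separate as
cleanly.

## Problem sizes and determinism

The validation runs use 25 components × 8 questions (200 items), 30–40
students and 4 models — comfortably the scale of a real exam cycle — and
fixed seeds throughout; property tests are derandomized. The end-to-end
pipeline on that scale runs in seconds.

## Known limitations

* The two presentation formats (full-context vs sequential) are carried as
  metadata and can be filtered on, but are never scored differently;
  conflicting duplicate records for the same responder and question are an
  error rather than being averaged.
* The subjective-ambiguity tag inherits whatever criteria the responding
  models used to self-report; it is the least transparent of the four tags.
* Quality scores aggregate within components only; no exam-level composite
  beyond listing components is computed.
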