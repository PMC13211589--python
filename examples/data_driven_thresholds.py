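"""Pick tagging thresholds from the data with elbow-point detection.

The tag criteria use fixed cutoffs (ensemble mean < 0.5, SD split at 0.3),
but the knee of each metric's sorted distribution offers a data-driven
sanity check: the point where values transition from typical to anomalous.
"""

from examaudit import elbow_threshold, grade_all, summarize_all
from examaudit.simulate import SimulationConfig, simulate_exam

config = SimulationConfig(n_components=25, questions_per_component=8, seed=0)
bank, truth, students, models = simulate_exam(config)
graded = grade_all(bank.by_id, models)
metrics = summarize_all(bank.questions, graded, models)

for name in ("sd_score", "mean_score"):
    values = [getattr(m, name) for m in metrics]
    knee = elbow_threshold(values)
    shown = "none (distribution too flat)" if knee is None else f"{knee:.3f}"
    print(f"elbow of sorted {name:11s}: {shown}")

# The knee of the SD distribution approximates the incoherence split; the
# fixed defaults (0.5 / 0.3) remain canonical, elbow output is advisory.
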