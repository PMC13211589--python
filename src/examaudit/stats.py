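"""Two-sample comparisons with a normality-gated test choice.

The comparison protocol: descriptives per group (mean, SD, median,
quartiles, min, max); a Shapiro-Wilk normality check on each group at
alpha = 0.05; a two-tailed Student t test when both groups look normal,
otherwise a two-sided Mann-Whitney U test (exact null distribution when
both groups are small and untied, normal approximation with continuity and
tie correction otherwise).  P below .05 is called significant.

Comparing a 4-member model ensemble against a student cohort is
statistically fragile; a warning is emitted when either group has fewer
than 5 observations, but the comparison is still computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "Descriptives",
    "ComparisonResult",
    "SmallSampleWarning",
    "describe",
    "compare",
]

ALPHA = 0.05


class SmallSampleWarning(UserWarning):
    """A group has too few observations for a stable comparison."""


@dataclass(frozen=True)
class Descriptives:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    min: float
    max: float


@dataclass(frozen=True)
class ComparisonResult:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    test_used: str  # "t_test" | "mann_whitney"
    statistic: float
    p_value: float
    significant: bool
    descriptives_a: Descriptives
    descriptives_b: Descriptives

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")
        if self.significant != (self.p_value < ALPHA):
            raise ValueError("significant flag inconsistent with p_value")


def describe(scores) -> Descriptives:
    """Mean, SD, median, linear-interpolation quartiles, min, max."""
    x = np.asarray(list(scores), dtype=float)
    if x.size == 0:
        raise ValueError("cannot describe an empty sample")
    return Descriptives(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        median=float(np.median(x)),
        q1=float(np.percentile(x, 25)),
        q3=float(np.percentile(x, 75)),
        min=float(np.min(x)),
        max=float(np.max(x)),
    )


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    # Shapiro-Wilk is undefined on (near-)constant samples; treat those as
    # non-normal so the rank test handles them.
    if np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sps.shapiro(x).pvalue > alpha


def _mann_whitney(a: np.ndarray, b: np.ndarray):
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if max(a.size, b.size) <= 8 and not has_ties:
        return sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    return sps.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )


def compare(
    sample_a,
    sample_b,
    gate: str = "auto",
    labels: tuple[str, str] = ("a", "b"),
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Compare two score samples with the normality-gated test choice.

    ``gate``: "auto" applies Shapiro-Wilk to each group (needs n >= 3 in
    both); "force_t" / "force_mw" pick the test directly.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if min(a.size, b.size) < 5:
        warnings.warn(
            f"group sizes ({a.size}, {b.size}) below 5: the comparison is "
            "computed but fragile",
            SmallSampleWarning,
            stacklevel=2,
        )
    if gate == "auto":
        if min(a.size, b.size) < 3:
            raise ValueError(
                "auto gating needs n >= 3 per group; pass gate='force_t' or "
                "gate='force_mw' explicitly"
            )
        use_t = _is_normal(a, alpha) and _is_normal(b, alpha)
    elif gate == "force_t":
        use_t = True
    elif gate == "force_mw":
        use_t = False
    else:
        raise ValueError(f"unknown gate {gate!r}")
    if use_t:
        res = sps.ttest_ind(a, b, equal_var=True)
        test_used = "t_test"
    else:
        res = _mann_whitney(a, b)
        test_used = "mann_whitney"
    p = float(res.pvalue)
    return ComparisonResult(
        label_a=labels[0],
        label_b=labels[1],
        n_a=int(a.size),
        n_b=int(b.size),
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=p,
        significant=p < alpha,
        descriptives_a=describe(a),
        descriptives_b=describe(b),
    )
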