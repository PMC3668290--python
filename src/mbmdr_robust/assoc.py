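"""Two-group association tests used inside MB-MDR.

Both the classical pooled-variance Student's t-test and Welch's
unequal-variance t-test are exposed; each result also carries the squared
statistic (the two-group ANOVA F value) because MB-MDR reports its final
epistasis evidence on the F scale.

Degenerate comparisons (zero variance on both sides) yield an invalid result
with ``f_value = 0`` and ``p_value = 1`` instead of raising, so that sparse
multilocus genotype cells never abort a genome scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TestResult", "InsufficientDataError", "student_t", "welch_t", "get_test"]


class InsufficientDataError(ValueError):
    """A group has fewer than two observations."""


@dataclass(frozen=True)
class TestResult:
    """Signed t statistic with its squared (F) value, df and two-sided p."""

    statistic: float
    f_value: float
    df: float
    p_value: float
    valid: bool


def _check_groups(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least two observations")
    return a, b


def _finish(t: float, df: float, p: float) -> TestResult:
    if not np.isfinite(t):  # zero variance in both groups
        return TestResult(statistic=0.0, f_value=0.0, df=df, p_value=1.0, valid=False)
    return TestResult(statistic=float(t), f_value=float(t) ** 2, df=float(df),
                      p_value=float(p), valid=True)


def student_t(a, b) -> TestResult:
    """Pooled-variance two-sample t-test; df = n_a + n_b - 2.

    The sign is positive when mean(a) > mean(b).
    """
    a, b = _check_groups(a, b)
    res = stats.ttest_ind(a, b, equal_var=True)
    return _finish(res.statistic, a.size + b.size - 2, res.pvalue)


def welch_t(a, b) -> TestResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    a, b = _check_groups(a, b)
    res = stats.ttest_ind(a, b, equal_var=False)
    df = res.df if np.isfinite(res.df) else float("nan")
    return _finish(res.statistic, df, res.pvalue)


def get_test(kind: str):
    """Return the test callable for 'student' or 'welch'."""
    if kind == "student":
        return student_t
    if kind == "welch":
        return welch_t
    raise ValueError(f"unknown test kind {kind!r}; expected 'student' or 'welch'")
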