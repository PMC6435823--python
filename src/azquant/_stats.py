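"""Shared normality-gated test selection used by plasticity and ephys summaries."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats


def is_normal(values: np.ndarray, alpha: float = 0.05) -> bool:
    """Normality gate: D'Agostino-Pearson omnibus test when the sample is
    large enough (n >= 8), Shapiro-Wilk fallback for small samples."""
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(x) >= 8:
            _, p = stats.normaltest(x)
        else:
            _, p = stats.shapiro(x)
    return p > alpha


def unpaired_test(a, b, alpha: float = 0.05) -> tuple[str, float, float]:
    """Choose and run an unpaired two-sample test.

    Both samples normal -> Student's t, or Welch's t when Levene's test
    rejects equal variances; otherwise Mann-Whitney U. Returns
    ``(test_name, statistic, p)`` with a two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.array_equal(a, b):
        return "degenerate", float("nan"), 1.0
    if is_normal(a, alpha) and is_normal(b, alpha):
        _, p_var = stats.levene(a, b)
        if p_var < alpha:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            return "welch_t", float(t), float(p)
        t, p = stats.ttest_ind(a, b, equal_var=True)
        return "student_t", float(t), float(p)
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return "mann_whitney", float(u), float(p)
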