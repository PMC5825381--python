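"""Group-level inference on decoding accuracies.

Accuracies are compared to the 1/3 chance level with one-tailed
one-sample t-tests (the only interesting direction is above chance),
condition and study contrasts use two-tailed paired t-tests, and
omnibus comparisons use a within-subject (repeated-measures) one-way
ANOVA.  No multiple-comparison correction is applied; a fixed p < 0.05
threshold is assumed by the callers, and reports carry the number of
tests run.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def t_one_sample(
    values, mu: float, one_tailed: bool = True
) -> tuple[float, int, float]:
    """One-sample t-test of ``values`` against ``mu``.

    The one-tailed p (default) is for mean > mu, the direction relevant
    when asking whether decoding beats chance.  Returns (t, df, p).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    if np.std(values, ddof=1) <= 1e-12 * max(1.0, abs(np.mean(values))):
        raise ValueError("zero variance")
    alternative = "greater" if one_tailed else "two-sided"
    res = stats.ttest_1samp(values, mu, alternative=alternative)
    return float(res.statistic), len(values) - 1, float(res.pvalue)


def t_paired(a, b, two_tailed: bool = True) -> tuple[float, int, float]:
    """Paired t-test (one-sample t on the differences a - b vs 0)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    diffs = a - b
    if np.std(diffs, ddof=1) <= 1e-12 * max(1.0, abs(np.mean(diffs))):
        raise ValueError("zero variance of differences")
    alternative = "two-sided" if two_tailed else "greater"
    res = stats.ttest_rel(a, b, alternative=alternative)
    return float(res.statistic), len(a) - 1, float(res.pvalue)


def rm_anova_oneway(matrix) -> tuple[float, int, int, float]:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix.

    Subject main effects are removed, F = MS_condition / MS_error with
    df1 = c - 1 and df2 = (n - 1)(c - 1).  For two conditions F equals
    the squared paired t on the same data.  Returns (F, df1, df2, p).
    No sphericity correction is applied.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be subjects x conditions")
    if np.isnan(matrix).any():
        raise ValueError("missing cells are not supported")
    n, c = matrix.shape
    if n < 2 or c < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = matrix.mean()
    subj_mean = matrix.mean(axis=1, keepdims=True)
    cond_mean = matrix.mean(axis=0, keepdims=True)
    ss_cond = n * np.sum((cond_mean - grand) ** 2)
    resid = matrix - subj_mean - cond_mean + grand
    ss_err = np.sum(resid**2)
    df1 = c - 1
    df2 = (n - 1) * (c - 1)
    ss_tot = np.sum((matrix - grand) ** 2)
    eps = 1e-12 * max(1.0, ss_tot)
    if ss_cond < eps:
        return 0.0, df1, df2, 1.0
    if ss_err < eps:
        raise ValueError("zero error variance")
    f = (ss_cond / df1) / (ss_err / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def interaction_2x2_within(a1, a2, b1, b2) -> tuple[float, int, int, float]:
    """Study x condition interaction for a fully within-subject 2x2.

    Computed as the squared paired t on the difference-of-differences
    (a1 - a2) - (b1 - b2), which equals the interaction F with df1 = 1
    and df2 = n - 1.
    """
    t, df, p = t_paired(
        np.asarray(a1) - np.asarray(a2), np.asarray(b1) - np.asarray(b2)
    )
    return t * t, 1, df, p
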