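"""Group statistics: within-subject standard errors and paired contrasts."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps


def within_subject_se(values: np.ndarray) -> np.ndarray:
    """Within-subject SE per condition for repeated-measures error bars.

    ``values`` is (subjects, conditions). Each subject's row is re-centered
    on the grand mean (removing per-subject offsets) before computing the
    per-condition standard error of the mean, so the error bars reflect the
    condition differences that paired tests evaluate; the usual
    ``sqrt(C / (C - 1))`` correction undoes the variance lost to the
    per-subject centering. Pure between-subject offsets yield SE = 0;
    independent noise recovers the ordinary SE.
    """
    values = np.asarray(values, float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("values must be (>=2 subjects, >=2 conditions)")
    n, c = values.shape
    centered = values - values.mean(axis=1, keepdims=True) + values.mean()
    return centered.std(axis=0, ddof=1) / np.sqrt(n) * np.sqrt(c / (c - 1))


def paired_t(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, int, float]:
    """Two-tailed paired t-test; returns (t, df, p) with df = n - 1.

    Zero-variance nonzero differences are degenerate (t infinite); they are
    flagged with a warning and reported as p = 0. Identical samples give
    t = 0, p = 1.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    d = a - b
    df = len(d) - 1
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, df, 1.0
        warnings.warn("zero-variance nonzero differences: degenerate paired t")
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    res = sps.ttest_rel(a, b)
    return float(res.statistic), df, float(res.pvalue)
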