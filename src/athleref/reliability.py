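"""Measurement reliability: ICC(3,1) and the within-subject CV.

ICC(3,1) is the two-way mixed-model, single-measures intraclass
correlation in its consistency form: the rater/occasion main effect is
excluded from the error term, so adding a constant to one column does not
lower agreement.  The within-subject coefficient of variation is the
root-mean within-subject SD expressed as a percentage of the grand mean —
the standard test–retest precision summary for repeated scans.
"""

from __future__ import annotations

import numpy as np

__all__ = ["icc_3_1", "within_subject_cv"]


def _as_matrix(data) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("repeated-measures data must be a 2-D matrix (subjects x occasions)")
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 occasions")
    if not np.all(np.isfinite(x)):
        raise ValueError("repeated-measures data must have no missing cells")
    return x


def icc_3_1(data) -> float:
    """ICC(3,1): (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error).

    Mean squares come from the two-way ANOVA decomposition with subjects
    and occasions as crossed factors; the occasion main effect is removed
    from the error (consistency form).

    Raises
    ------
    ValueError
        Fewer than 2 subjects/occasions, missing cells, or zero total
        variance (the coefficient is undefined).
    """
    x = _as_matrix(data)
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom == 0:
        raise ValueError("zero subject and error variance: ICC undefined")
    return float((ms_rows - ms_err) / denom)


def within_subject_cv(data) -> float:
    """Within-subject (root-mean-square) CV, percent.

    100 * sqrt(mean of per-subject variances over repeats) / grand mean.
    For duplicate measurements the per-subject variance is d**2 / 2 with
    d the within-pair difference.  Requires strictly positive values.
    """
    x = _as_matrix(data)
    if np.any(x <= 0):
        raise ValueError("within-subject CV requires strictly positive measurements")
    per_subject_var = x.var(axis=1, ddof=1)
    sw = np.sqrt(per_subject_var.mean())
    return float(100.0 * sw / x.mean())
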