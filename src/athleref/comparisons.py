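"""Group comparisons: sex differences within sport and sport differences
within sex, reported with nominal (unadjusted) p-values.

Sex comparisons use an unpaired t-test when both groups pass a
Shapiro-Wilk normality check, otherwise the Mann-Whitney U test.  Sport
comparisons use the Kruskal-Wallis omnibus with Dunn's rank-mean post-hoc
z-tests (tie-corrected).  No multiplicity adjustment is applied anywhere;
every p-value is nominal by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ComparisonResult", "sex_difference", "sport_differences", "dunn_pairwise"]


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    p_value: float  # nominal, unadjusted
    groups: tuple
    n: tuple
    pairwise: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def sex_difference(
    values_f,
    values_m,
    *,
    normality_alpha: float = 0.05,
    equal_var: bool = False,
) -> ComparisonResult:
    """Compare an outcome between females and males.

    Both groups are screened with Shapiro-Wilk at ``normality_alpha``; if
    both look Gaussian an unpaired t-test runs (Welch by default), else the
    Mann-Whitney U test.  The chosen branch is recorded in ``test``.
    """
    f = np.asarray(values_f, dtype=float)
    m = np.asarray(values_m, dtype=float)
    if f.size < 2 or m.size < 2:
        raise ValueError("each group needs at least 2 observations")
    # Shapiro-Wilk is undefined for constant samples; a constant sample is
    # treated as failing the normality gate.
    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0 or x.size < 3:
            return False
        return stats.shapiro(x).pvalue > normality_alpha

    if _normal(f) and _normal(m):
        res = stats.ttest_ind(f, m, equal_var=equal_var)
        name = "t" if equal_var else "welch_t"
    else:
        res = stats.mannwhitneyu(f, m, alternative="two-sided")
        name = "mannwhitneyu"
    return ComparisonResult(
        test=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        groups=("female", "male"),
        n=(int(f.size), int(m.size)),
    )


def _tie_term(all_values: np.ndarray) -> float:
    _, counts = np.unique(all_values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def dunn_pairwise(groups: Mapping[object, Sequence[float]]) -> pd.DataFrame:
    """Dunn's post-hoc z statistics for all group pairs.

    Ranks are pooled over all groups; for a pair (i, j) the statistic is
    the difference of mean ranks divided by its tie-corrected standard
    error sqrt((N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j)) with
    T = sum(t^3 - t) over tie blocks.  Two-sided normal p-values, nominal.
    """
    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    pooled = np.concatenate(samples)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [s.size for s in samples]
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start : start + sz].mean())
        start += sz
    tie_correction = _tie_term(pooled) / (12.0 * (N - 1.0))
    base_var = N * (N + 1.0) / 12.0 - tie_correction
    rows = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append(
                {
                    "group_a": labels[a],
                    "group_b": labels[b],
                    "z": float(z),
                    "p_value": float(min(p, 1.0)),
                    "n_a": sizes[a],
                    "n_b": sizes[b],
                }
            )
    return pd.DataFrame(rows)


def sport_differences(groups: Mapping[object, Sequence[float]]) -> ComparisonResult:
    """Kruskal-Wallis omnibus across sports plus Dunn pairwise tests.

    Requires at least 3 groups with n >= 2 each; the tie-corrected H
    statistic comes from scipy, the pairwise table from
    :func:`dunn_pairwise`.  All p-values nominal.
    """
    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(labels) < 3 or any(s.size < 2 for s in samples):
        raise ValueError("omnibus test requires >= 3 groups with n >= 2 each")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    return ComparisonResult(
        test="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        groups=tuple(labels),
        n=tuple(int(s.size) for s in samples),
        pairwise=dunn_pairwise(groups),
    )
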