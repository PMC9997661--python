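"""Shared statistical utilities and tumor scoring.

Weighted histoscore, Pearson chi-squared on contingency tables, two-tailed
Mann-Whitney, one-way ANOVA, pooled-variance Student's t, and Bonferroni
adjustment.  The hypothesis tests defer to :mod:`scipy.stats`; the wrappers
fix the conventions used throughout the package (no continuity correction
for chi-squared, exact Mann-Whitney for small untied samples, pooled
variance for t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StainAreaFractions",
    "histoscore",
    "pearson_chi_squared",
    "mann_whitney_u",
    "one_way_anova",
    "student_t_test",
    "bonferroni_adjust",
]


@dataclass(frozen=True)
class StainAreaFractions:
    """Percent tumor area with weak / moderate / strong DAB staining.

    The negative fraction fills the remainder to 100% and does not enter
    the score.
    """

    percent_weak: float
    percent_moderate: float
    percent_strong: float

    def __post_init__(self) -> None:
        for name in ("percent_weak", "percent_moderate", "percent_strong"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        total = self.percent_weak + self.percent_moderate + self.percent_strong
        if total > 100.0 + 1e-6:
            raise ValueError(
                f"stain fractions sum to {total:.6g} > 100"
            )


def histoscore(fractions: StainAreaFractions) -> float:
    """Weighted histoscore: 1*%weak + 2*%moderate + 3*%strong, range 0-300."""
    return (
        1.0 * fractions.percent_weak
        + 2.0 * fractions.percent_moderate
        + 3.0 * fractions.percent_strong
    )


def pearson_chi_squared(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an r x c count table.

    No continuity correction (Yates) is applied; df = (r-1)(c-1).

    Returns ``(chi2, df, p)``.  Raises if any expected count is zero
    (degenerate margin).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    if obs.sum() <= 0:
        raise ValueError("empty table")
    expected = stats.contingency.expected_freq(obs)
    if (expected <= 0).any():
        raise ValueError("zero margin: expected count of 0")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def mann_whitney_u(
    x, y, alternative: str = "two-sided", exact_threshold: int = 12
) -> tuple[float, float]:
    """Mann-Whitney U with midrank ties.

    Exact p by enumeration when the combined sample size is at most
    ``exact_threshold`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.

    Returns ``(U, p)`` where U is the statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= exact_threshold and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def one_way_anova(*groups) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA.  Returns ``(F, df_between, df_within, p)``.

    A fully degenerate input (zero between- and within-group variance) is
    reported as F = 0, p = 1 rather than NaN.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    k = len(arrays)
    n = sum(g.size for g in arrays)
    df1, df2 = k - 1, n - k
    grand = np.concatenate(arrays).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def student_t_test(x, y, two_tailed: bool = True) -> tuple[float, int, float]:
    """Two-sample pooled-variance Student's t test.

    Returns ``(t, df, p)`` with df = n_x + n_y - 2.  Zero pooled variance
    with equal means is reported as t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    df = x.size + y.size - 2
    sp2 = (
        ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    ) / df
    if sp2 == 0.0:
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        t = float("inf") if x.mean() > y.mean() else float("-inf")
        return t, df, 0.0
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / x.size + 1 / y.size))
    if two_tailed:
        p = 2.0 * float(stats.t.sf(abs(t), df))
    else:
        p = float(stats.t.sf(t, df))
    return float(t), df, p


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p*m) elementwise.

    ``m`` defaults to the number of p-values supplied.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)
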