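"""Shared statistical kernel.

Thin, uniformly typed wrappers around the classical tests the analyses
rely on: two-sample t (pooled or Welch), Pearson and partial correlation,
one-way ANOVA with Tukey HSD post-hoc, and the Pearson chi-square test of
independence (no continuity correction).  Each returns a
:class:`TestResult` so module reports serialise identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, InsufficientCohortError


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``estimate`` holds the natural effect estimate where one exists (mean
    difference, correlation coefficient); ``df`` is a float or a pair.
    """

    statistic: float
    df: float | tuple[float, float]
    p: float
    method: str
    estimate: float | None = None
    ci: tuple[float, float] | None = None
    extra: dict = field(default_factory=dict)


def _clip_p(p: float) -> float:
    # p is reported in (0, 1]; exact zeros only arise from underflow
    return float(min(max(p, np.nextafter(0.0, 1.0)), 1.0))


def two_sample_t(x, y, pooled: bool = True) -> TestResult:
    """Two-sided two-sample t-test; pooled variance by default, Welch optional.

    Two constant, equal samples are reported as t = 0, p = 1 rather than an
    error.  Samples of fewer than 2 observations raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientCohortError(
            f"two_sample_t needs n >= 2 per sample, got {len(x)} and {len(y)}"
        )
    diff = float(np.mean(x) - np.mean(y))
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if diff == 0:
            df = len(x) + len(y) - 2 if pooled else float(len(x) + len(y) - 2)
            return TestResult(0.0, float(df), 1.0,
                              "student-t" if pooled else "welch-t", estimate=0.0)
        raise DegenerateInputError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    return TestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p=_clip_p(float(res.pvalue)),
        method="student-t" if pooled else "welch-t",
        estimate=diff,
    )


def pearson(x, y) -> TestResult:
    """Pearson correlation with the two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientCohortError("pearson needs aligned samples with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateInputError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return TestResult(
        statistic=float(res.statistic),
        df=float(len(x) - 2),
        p=_clip_p(float(res.pvalue)),
        method="pearson",
        estimate=float(res.statistic),
    )


def partial_correlation(x, y, z) -> TestResult:
    """First-order partial correlation r_xy.z with a t test on n−3 df.

    Uses the recursion r_xy.z = (r_xy − r_xz·r_yz) / sqrt((1−r_xz²)(1−r_yz²)),
    equivalent to correlating the residuals of x~z and y~z.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(x)
    if not (len(y) == len(z) == n) or n < 4:
        raise InsufficientCohortError("partial_correlation needs aligned samples, n >= 4")
    r_xy = pearson(x, y).estimate
    r_xz = pearson(x, z).estimate
    r_yz = pearson(y, z).estimate
    denom_sq = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom_sq <= 0:
        raise DegenerateInputError(
            "a conditioning correlation is ±1; partial correlation degenerate"
        )
    r = (r_xy - r_xz * r_yz) / np.sqrt(denom_sq)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) == 1.0:
        t, p = np.inf, 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), _clip_p(p), "partial-pearson", estimate=r)


def _prepare_groups(groups):
    cleaned, dropped = [], 0
    for g in groups:
        g = np.asarray(g, dtype=float)
        if len(g) < 2:
            dropped += 1
            continue
        cleaned.append(g)
    if dropped:
        warnings.warn(f"dropped {dropped} group(s) with fewer than 2 observations",
                      stacklevel=3)
    if len(cleaned) < 2:
        raise InsufficientCohortError("need >= 2 groups with >= 2 observations each")
    return cleaned


def anova_oneway(groups) -> TestResult:
    """One-way ANOVA F-test; groups of fewer than 2 observations are dropped."""
    cleaned = _prepare_groups(groups)
    k = len(cleaned)
    n_total = sum(len(g) for g in cleaned)
    res = sps.f_oneway(*cleaned)
    return TestResult(
        statistic=float(res.statistic),
        df=(float(k - 1), float(n_total - k)),
        p=_clip_p(float(res.pvalue)),
        method="anova-oneway",
    )


def tukey_hsd(groups, labels=None) -> list[TestResult]:
    """All pairwise Tukey HSD comparisons (studentized-range adjusted p).

    Returns one :class:`TestResult` per unordered pair (i < j); ``extra``
    carries the pair labels and the adjusted confidence interval.
    """
    cleaned = _prepare_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(cleaned))]
    res = sps.tukey_hsd(*cleaned)
    ci = res.confidence_interval(0.95)
    out = []
    for i in range(len(cleaned)):
        for j in range(i + 1, len(cleaned)):
            out.append(TestResult(
                statistic=float(res.statistic[i, j]),
                df=float(sum(len(g) for g in cleaned) - len(cleaned)),
                p=_clip_p(float(res.pvalue[i, j])),
                method="tukey-hsd",
                estimate=float(np.mean(cleaned[i]) - np.mean(cleaned[j])),
                ci=(float(ci.low[i, j]), float(ci.high[i, j])),
                extra={"pair": (labels[i], labels[j])},
            ))
    return out


def chi_square(table) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction.

    ``extra`` reports the expected counts and a ``low_expected`` flag when
    any expected cell count falls below 5.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise DegenerateInputError("need a 2-D table of non-negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateInputError("contingency table has a zero margin")
    if min(table.shape) < 2:
        raise DegenerateInputError("need >= 2 levels on both axes")
    stat, p, dof, expected = sps.chi2_contingency(table, correction=False)
    return TestResult(
        statistic=float(stat),
        df=float(dof),
        p=_clip_p(float(p)),
        method="pearson-chi2",
        extra={"expected": expected, "low_expected": bool((expected < 5).any())},
    )
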