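"""Normality-gated two-sample inference and related statistics.

The workflow mirrors standard practice in small-sample physiology:

1. Shapiro-Wilk on each group at alpha = 0.05.
2. Both normal -> two-tailed F test of variance equality, then Student's
   (equal variances) or Welch's unpaired two-tailed t test; means +/- SD are
   the reported summaries.
3. Either group non-normal -> two-tailed Mann-Whitney; medians are the
   reported summaries.
4. Bonferroni over the m comparisons sharing a dataset: on the parametric
   path alpha is divided by m; on the nonparametric path the significance
   threshold for p is divided by m.  The two rules are the same decision
   rule (p < 0.05/m) and both quantities are recorded.

Also provides summary-statistic t tests (for published mean/SD/n triples),
paired t tests for densitometry, and ordinary least-squares lines with
adjusted R^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SampleSummary",
    "StatResult",
    "LinearFitResult",
    "normality_gate",
    "mann_whitney",
    "two_sample_compare",
    "t_from_summary",
    "paired_compare",
    "linear_fit",
]

ALPHA = 0.05
EXACT_MW_LIMIT = 400  # n1*n2 at or below which the exact MW null is enumerated


@dataclass(frozen=True)
class SampleSummary:
    n: int
    mean: float
    sd: float
    median: float = math.nan

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_sample(cls, x: Sequence[float]) -> "SampleSummary":
        x = np.asarray(x, float)
        return cls(n=x.size, mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)), median=float(np.median(x)))


@dataclass
class StatResult:
    """Outcome of one gated two-sample comparison."""

    test_name: str
    statistic: float
    p_two_tailed: float
    significant: bool
    alpha_effective: float
    m_comparisons: int
    normal_flags: tuple = (True, True)
    variance_equal: bool | None = None
    U_first_group: float | None = None
    U_second_group: float | None = None
    summaries: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_tailed <= 1.0):
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class LinearFitResult:
    slope: float
    intercept: float
    adj_R2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.adj_R2 > 1 + 1e-12:
            raise ValueError("adjusted R^2 cannot exceed 1")


def _shapiro_normal(x: np.ndarray, alpha: float = ALPHA) -> bool:
    """Shapiro-Wilk normality decision; a constant sample counts as non-normal."""
    if np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = sps.shapiro(x)
    return bool(p > alpha)


def normality_gate(x: Sequence[float], y: Sequence[float], alpha: float = ALPHA) -> tuple:
    """Per-group Shapiro-Wilk decisions; both must be True for the t-test path."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 3 or y.size < 3:
        raise ValueError("Shapiro-Wilk requires n >= 3 per group")
    return _shapiro_normal(x, alpha), _shapiro_normal(y, alpha)


def _f_test_equal_var(x: np.ndarray, y: np.ndarray) -> tuple:
    """Two-tailed F test of variance equality; returns (F, p)."""
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    if v1 == 0 and v2 == 0:
        return math.nan, 1.0
    if v2 == 0 or v1 == 0:
        return math.inf, 0.0
    F = v1 / v2
    df1, df2 = x.size - 1, y.size - 1
    cdf = sps.f.cdf(F, df1, df2)
    return float(F), float(2.0 * min(cdf, 1.0 - cdf))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Two-tailed Mann-Whitney; returns (U1, U2, p).

    The exact null distribution is used when ``n1*n2 <= 400`` and there are
    no ties; otherwise the normal approximation with tie and continuity
    corrections.  ``U1 + U2 == n1*n2`` always.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.ptp(np.concatenate([x, y])) == 0:
        # All observations tied: no evidence of a shift in either direction.
        half = x.size * y.size / 2.0
        return half, half, 1.0
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    U1 = float(res.statistic)
    return U1, float(x.size * y.size) - U1, float(min(res.pvalue, 1.0))


def two_sample_compare(x: Sequence[float], y: Sequence[float], m_comparisons: int = 1) -> StatResult:
    """Full gated unpaired comparison of two samples.

    ``m_comparisons`` is the number of hypotheses tested on the same
    dataset; the decision threshold is ``0.05 / m`` on both paths.
    """
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    x, y = np.asarray(x, float), np.asarray(y, float)
    normal = normality_gate(x, y)
    alpha_eff = ALPHA / m_comparisons
    summaries = (SampleSummary.from_sample(x), SampleSummary.from_sample(y))
    if all(normal):
        _, p_var = _f_test_equal_var(x, y)
        equal_var = p_var >= ALPHA
        t, p = sps.ttest_ind(x, y, equal_var=equal_var)
        return StatResult(
            test_name="student_t" if equal_var else "welch_t",
            statistic=float(t), p_two_tailed=float(p),
            significant=bool(p < alpha_eff),
            alpha_effective=alpha_eff, m_comparisons=m_comparisons,
            normal_flags=normal, variance_equal=equal_var, summaries=summaries,
        )
    U1, U2, p = mann_whitney(x, y)
    return StatResult(
        test_name="mann_whitney", statistic=U1, p_two_tailed=p,
        significant=bool(p < alpha_eff),
        alpha_effective=alpha_eff, m_comparisons=m_comparisons,
        normal_flags=normal, U_first_group=U1, U_second_group=U2, summaries=summaries,
    )


def t_from_summary(s1: SampleSummary, s2: SampleSummary, equal_var: bool = True) -> tuple:
    """Unpaired two-tailed t test from (n, mean, sd) summaries only.

    Returns ``(t, df, p)``.  Matches the raw-sample test exactly whenever
    the raw samples share these summaries, which allows published
    mean +/- SD tables to be re-tested without the underlying data.
    """
    if s1.sd == 0 and s2.sd == 0:
        raise ValueError("both variances are zero")
    if equal_var:
        df = s1.n + s2.n - 2
        sp2 = ((s1.n - 1) * s1.sd**2 + (s2.n - 1) * s2.sd**2) / df
        se = math.sqrt(sp2 * (1.0 / s1.n + 1.0 / s2.n))
    else:
        a, b = s1.sd**2 / s1.n, s2.sd**2 / s2.n
        se = math.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (s1.n - 1) + b**2 / (s2.n - 1))
    t = (s1.mean - s2.mean) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def paired_compare(x: Sequence[float], y: Sequence[float], m_comparisons: int = 1) -> StatResult:
    """Two-tailed paired t test on per-pair differences (e.g. same-slide pairs)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            t, p = 0.0, 1.0
        else:
            raise ValueError("pair differences have zero variance but nonzero mean")
    else:
        t, p = sps.ttest_rel(x, y)
    alpha_eff = ALPHA / m_comparisons
    return StatResult(
        test_name="paired_t", statistic=float(t), p_two_tailed=float(p),
        significant=bool(p < alpha_eff), alpha_effective=alpha_eff,
        m_comparisons=m_comparisons,
        summaries=(SampleSummary.from_sample(x), SampleSummary.from_sample(y)),
    )


def linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearFitResult:
    """Ordinary least-squares line with adjusted R^2 = 1-(1-R^2)(n-1)/(n-2)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    n = x.size
    adj = 1.0 - (1.0 - res.rvalue**2) * (n - 1) / (n - 2)
    return LinearFitResult(slope=float(res.slope), intercept=float(res.intercept), adj_R2=float(adj), n_points=n)
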