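"""Group statistics: summary-statistic and raw-data t-tests, one-way ANOVA
with Tukey HSD, pooled summaries, and the count normalizations used alongside
them.

Many published comparisons are only recoverable from printed
"mean +/- SD (n)" triples, so every two-sample test exists in a
summary-statistic form (:func:`t_from_summary`) of which the raw-data form
(:func:`t_unpaired`) is, by construction, an exact special case.

Conventions: all p-values are two-sided; the default unpaired variant is the
pooled (Student) t-test; Welch uses the Satterthwaite degrees of freedom;
Tukey-adjusted p-values come from the studentized range distribution and use
the Tukey-Kramer standard error for unbalanced groups.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "TestResult",
    "summary_of",
    "t_from_summary",
    "t_unpaired",
    "t_paired",
    "anova_oneway",
    "tukey_hsd",
    "pooled_group_summary",
    "positive_ratio",
    "organoid_norm",
]


@dataclass(frozen=True)
class GroupSummary:
    """A printed (mean, sample SD, n) triple."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test.

    ``df`` is a float for t-tests and a ``(df_between, df_within)`` pair for
    ANOVA / Tukey; ``pair`` identifies the group indices of a pairwise
    comparison.
    """

    statistic: float
    df: float | tuple[float, float]
    p: float
    method: str
    pair: tuple[int, int] | None = None

    def rounded(self, ndigits: int = 2) -> "TestResult":
        """Presentation copy with the p-value rounded (e.g. "p = 0.02")."""
        return TestResult(self.statistic, self.df, round(self.p, ndigits),
                          self.method, self.pair)


def summary_of(x) -> GroupSummary:
    """Sample summary (mean, SD with n-1 denominator, n) of raw data."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("empty sample")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return GroupSummary(float(x.mean()), sd, int(x.size))


def _two_sided_t_p(t: float, df: float) -> float:
    return float(2.0 * sps.t.sf(abs(t), df))


def t_from_summary(a: GroupSummary, b: GroupSummary,
                   variant: str = "student") -> TestResult:
    """Two-sample t-test from (mean, SD, n) summaries.

    variant="student": pooled variance, df = n_a + n_b - 2.
    variant="welch":   unpooled variance, Satterthwaite df.

    Degenerate inputs (both SDs zero) use the conventions p = 1 for equal
    means and p = 0 otherwise, with a log record.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    diff = a.mean - b.mean
    if a.sd == 0 and b.sd == 0:
        if diff == 0:
            logger.info("degenerate t-test: zero variance, equal means -> p = 1")
            return TestResult(0.0, float(a.n + b.n - 2), 1.0, variant)
        logger.info("degenerate t-test: zero variance, unequal means -> p = 0")
        return TestResult(math.copysign(math.inf, diff),
                          float(a.n + b.n - 2), 0.0, variant)
    va, vb = a.sd ** 2, b.sd ** 2
    if variant == "student":
        df = float(a.n + b.n - 2)
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    else:
        wa, wb = va / a.n, vb / b.n
        se = math.sqrt(wa + wb)
        df = (wa + wb) ** 2 / (wa ** 2 / (a.n - 1) + wb ** 2 / (b.n - 1))
    t = diff / se
    return TestResult(float(t), float(df), _two_sided_t_p(t, df), variant)


def t_unpaired(x, y, variant: str = "student") -> TestResult:
    """Two-sample t-test on raw data; identical to :func:`t_from_summary`
    applied to the samples' own summaries."""
    return t_from_summary(summary_of(x), summary_of(y), variant)


def t_paired(pairs) -> TestResult:
    """Paired t-test: one-sample t on within-pair differences.

    Pairs with a missing member are dropped (logged).  All-identical nonzero
    differences give p = 0 by convention.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (u, v)")
    complete = arr[np.all(np.isfinite(arr), axis=1)]
    dropped = len(arr) - len(complete)
    if dropped:
        logger.info("paired t-test: dropped %d incomplete pair(s)", dropped)
    if len(complete) < 2:
        raise ValueError("paired t-test needs at least 2 complete pairs")
    d = complete[:, 0] - complete[:, 1]
    df = float(len(d) - 1)
    sd = float(d.std(ddof=1))
    md = float(d.mean())
    if sd == 0:
        if md == 0:
            return TestResult(0.0, df, 1.0, "paired")
        logger.info("degenerate paired t-test: identical nonzero differences -> p = 0")
        return TestResult(math.copysign(math.inf, md), df, 0.0, "paired")
    t = md / (sd / math.sqrt(len(d)))
    return TestResult(float(t), df, _two_sided_t_p(t, df), "paired")


def _anova_parts(groups):
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {i} has n < 2")
    ns = np.array([g.size for g in gs])
    means = np.array([g.mean() for g in gs])
    big_n = int(ns.sum())
    k = len(gs)
    grand = float(np.concatenate(gs).mean())
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    return gs, ns, means, k, big_n, ss_between, ss_within


def anova_oneway(groups) -> TestResult:
    """One-way ANOVA; F with (k-1, N-k) degrees of freedom.

    With two groups, F equals the square of the pooled t statistic and the
    p-values coincide.
    """
    _, _, _, k, big_n, ssb, ssw = _anova_parts(groups)
    df1, df2 = float(k - 1), float(big_n - k)
    if ssw == 0:
        p = 1.0 if ssb == 0 else 0.0
        f = 0.0 if ssb == 0 else math.inf
        logger.info("degenerate ANOVA: zero within-group variance")
        return TestResult(f, (df1, df2), p, "anova")
    f = (ssb / df1) / (ssw / df2)
    return TestResult(float(f), (df1, df2), float(sps.f.sf(f, df1, df2)), "anova")


def tukey_hsd(groups) -> list[TestResult]:
    """Tukey's HSD post-hoc test: all pairwise comparisons with adjusted
    p-values from the studentized range distribution with (k, N-k) parameters.

    Unbalanced groups use the Tukey-Kramer standard error
    ``sqrt(MSW/2 * (1/n_i + 1/n_j))``.  With k = 2 the adjusted p equals the
    pooled t-test p (q = t * sqrt(2)).
    """
    gs, ns, means, k, big_n, _, ssw = _anova_parts(groups)
    dfw = float(big_n - k)
    msw = ssw / dfw
    results = []
    for i, j in itertools.combinations(range(k), 2):
        if msw == 0:
            diff = means[i] - means[j]
            q = 0.0 if diff == 0 else math.inf
            p = 1.0 if diff == 0 else 0.0
        else:
            se = math.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            p = float(sps.studentized_range.sf(q, k, dfw))
        results.append(TestResult(float(q), (float(k), dfw),
                                  min(max(p, 0.0), 1.0), "tukey", pair=(i, j)))
    return results


def pooled_group_summary(parts) -> GroupSummary:
    """Combine (mean, SD, n) summaries as if their raw observations were
    pooled into one sample.

    combined mean = sum(n_i m_i) / N;
    combined variance = [sum((n_i-1) s_i^2) + sum(n_i (m_i - m)^2)] / (N - 1).
    """
    parts = list(parts)
    if not parts:
        raise ValueError("need at least one summary to pool")
    if len(parts) == 1:
        return parts[0]
    big_n = sum(p.n for p in parts)
    mean = sum(p.n * p.mean for p in parts) / big_n
    if big_n < 2:
        return GroupSummary(mean, 0.0, big_n)
    ss = sum((p.n - 1) * p.sd ** 2 for p in parts)
    ss += sum(p.n * (p.mean - mean) ** 2 for p in parts)
    return GroupSummary(float(mean), float(math.sqrt(ss / (big_n - 1))), int(big_n))


def positive_ratio(n_positive: int, n_negative: int) -> float:
    """Immunostain score: positive cells per *negative* cell (not per total)."""
    if n_positive < 0 or n_negative < 0:
        raise ValueError("counts must be non-negative")
    if n_negative == 0:
        raise ValueError("positive ratio undefined with zero negative cells")
    return n_positive / n_negative


def organoid_norm(start_count: int, end_count: int) -> float:
    """Normalize an organoid count to a start of 100: the start count is
    rescaled by a factor that maps it to 100 and the end count follows."""
    if start_count < 1:
        raise ValueError("start_count must be >= 1")
    if end_count < 0:
        raise ValueError("end_count must be >= 0")
    return end_count * (100.0 / start_count)
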