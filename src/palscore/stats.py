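"""Statistical toolkit for small stratified simulation cohorts.

Implements the tests and estimators used to compare two groups of teams:

* exact Fisher test for r x 2 contingency tables by full enumeration with
  the point-probability (two-sided) rule,
* difference of two proportions with Wald or Newcombe hybrid-score CI,
* Wilcoxon rank-sum (exact for small untied samples, tie-corrected normal
  approximation otherwise),
* Hodges-Lehmann location-shift estimate with CI by inversion of the exact
  Mann-Whitney null distribution,
* Lin's concordance correlation coefficient with a seeded case-resampling
  bootstrap CI,
* medians and interquartile ranges using the SAS empirical-distribution-
  with-averaging quantile rule (PCTLDEF=5).

All results are returned as :class:`StatResult` carrying the estimate, CI,
p-value and a method tag naming exactly what was computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import confint_proportions_2indep

__all__ = ["ContingencyTable", "StatResult", "fisher_exact",
           "proportion_difference", "wilcoxon_rank_sum", "hodges_lehmann",
           "lin_ccc", "bootstrap_ci", "lin_ccc_with_ci", "median_iqr",
           "QUANTILE_METHOD"]

#: numpy quantile method matching SAS PCTLDEF=5 (the rule used for all IQRs)
QUANTILE_METHOD = "averaged_inverted_cdf"

#: relative tolerance guard when comparing table point probabilities
_POINT_PROB_RTOL = 1e-7

#: enumeration guard: refuse Fisher tables with more observations than this
_FISHER_MAX_N = 500


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c count table with optional row/column labels."""

    counts: tuple
    row_labels: tuple | None = None
    col_labels: tuple | None = None

    def __post_init__(self):
        counts = tuple(tuple(int(x) for x in row) for row in self.counts)
        object.__setattr__(self, "counts", counts)
        if len(counts) < 2 or any(len(r) < 2 for r in counts):
            raise ValueError("table must be at least 2x2")
        if len({len(r) for r in counts}) != 1:
            raise ValueError("ragged table")
        if any(x < 0 for row in counts for x in row):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return sum(sum(r) for r in self.counts)


@dataclass(frozen=True)
class StatResult:
    method: str
    estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    n_resamples: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if (self.estimate is not None and self.ci_low is not None
                and self.ci_high is not None):
            if not (self.ci_low <= self.estimate + 1e-12
                    and self.estimate - 1e-12 <= self.ci_high):
                raise ValueError(
                    f"CI [{self.ci_low}, {self.ci_high}] does not bracket "
                    f"estimate {self.estimate}")


def _as_table(table) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    return ContingencyTable(tuple(tuple(row) for row in np.asarray(table)))


def fisher_exact(table) -> StatResult:
    """Exact two-sided Fisher test for an r x 2 table by full enumeration.

    The p-value sums the multivariate hypergeometric probabilities (fixed
    margins) of every table whose point probability does not exceed the
    observed one; a small relative tolerance absorbs would-be floating-point
    ties (the sums themselves are exact integer arithmetic).  Degenerate
    tables with a zero margin return p = 1 by convention.
    """
    ct = _as_table(table)
    rows = ct.counts
    if any(len(r) != 2 for r in rows):
        raise ValueError("fisher_exact requires an r x 2 table")
    if ct.n > _FISHER_MAX_N:
        raise ValueError(f"table total {ct.n} exceeds enumeration guard "
                         f"{_FISHER_MAX_N}")
    row_sums = [sum(r) for r in rows]
    col1 = sum(r[0] for r in rows)
    N = ct.n
    if 0 in row_sums or col1 == 0 or col1 == N or N == 0:
        return StatResult(method="fisher exact, full enumeration "
                                 "(degenerate margin)", p_value=1.0)

    denom = math.comb(N, col1)
    num_obs = math.prod(math.comb(rs, r[0]) for rs, r in zip(row_sums, rows))
    # integer threshold implementing prob <= obs * (1 + rtol), exact arithmetic
    thresh = num_obs + (num_obs // int(1 / _POINT_PROB_RTOL))
    suffix = [0] * (len(row_sums) + 1)
    for i in range(len(row_sums) - 1, -1, -1):
        suffix[i] = suffix[i + 1] + row_sums[i]

    total = 0

    def enumerate_rows(i, rem, num):
        nonlocal total
        if i == len(row_sums):
            if rem == 0 and num <= thresh:
                total += num
            return
        lo = max(0, rem - suffix[i + 1])
        hi = min(row_sums[i], rem)
        for k in range(lo, hi + 1):
            enumerate_rows(i + 1, rem - k, num * math.comb(row_sums[i], k))

    enumerate_rows(0, col1, 1)
    p = min(1.0, total / denom)
    return StatResult(method="fisher exact, full enumeration", p_value=p)


def proportion_difference(k1: int, n1: int, k2: int, n2: int,
                          method: str = "wald",
                          alpha: float = 0.05) -> StatResult:
    """Difference of two proportions, reported in percentage points.

    The estimate is ``100 * (k2/n2 - k1/n1)`` — group 2 minus group 1 —
    with a 95% CI by the selected binomial method (``wald`` or the Newcombe
    hybrid score interval).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    p1, p2 = k1 / n1, k2 / n2
    diff = p2 - p1
    z = sps.norm.ppf(1 - alpha / 2)
    if method == "wald":
        se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
        lo, hi = diff - z * se, diff + z * se
    elif method == "newcombe":
        lo, hi = confint_proportions_2indep(
            k2, n2, k1, n1, method="newcomb", compare="diff",
            alpha=alpha, correction=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    lo, hi = max(-1.0, lo), min(1.0, hi)
    return StatResult(method=f"difference of proportions, {method} CI",
                      estimate=100.0 * diff, ci_low=100.0 * lo,
                      ci_high=100.0 * hi)


def _has_ties(x, y) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def wilcoxon_rank_sum(x, y, exact_max_n: int = 25) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of the rank-sum distribution when the combined sample
    size is <= ``exact_max_n`` and there are no ties; tie-corrected normal
    approximation with continuity correction otherwise.  The method tag
    records which path was taken.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if x.size + y.size <= exact_max_n and not _has_ties(x, y):
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return StatResult(method="wilcoxon rank-sum, exact enumeration",
                          p_value=float(min(1.0, res.pvalue)))
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return StatResult(
        method="wilcoxon rank-sum, tie-corrected normal approximation",
        p_value=float(min(1.0, res.pvalue)))


@lru_cache(maxsize=256)
def _mann_whitney_counts(m: int, n: int):
    """Counts of rank configurations per Mann-Whitney U value (exact null).

    Returns an int64 array ``c`` of length m*n + 1 with ``c[u]`` = number of
    the C(m+n, m) equally likely rank assignments giving U = u.  Classic
    recursion N(m, n, u) = N(m-1, n, u-n) + N(m, n-1, u).
    """
    if m == 0 or n == 0:
        return np.ones(1, dtype=np.int64)
    a = _mann_whitney_counts(m - 1, n)   # length (m-1)*n + 1
    b = _mann_whitney_counts(m, n - 1)   # length m*(n-1) + 1
    out = np.zeros(m * n + 1, dtype=np.int64)
    out[n:n + a.size] += a
    out[:b.size] += b
    return out


def hodges_lehmann(x, y, alpha: float = 0.05,
                   exact_max_pairs: int = 2500) -> StatResult:
    """Hodges-Lehmann shift estimate for two samples, oriented y - x.

    The estimate is the median of all ``len(x) * len(y)`` pairwise
    differences ``y_j - x_i``.  The CI inverts the Mann-Whitney test at the
    95% level: with ``D_(1) <= ... <= D_(mn)`` the ordered differences, the
    interval is ``[D_(k+1), D_(mn-k)]`` where k is the largest integer with
    ``P(U <= k) <= alpha/2`` under the exact null distribution (normal
    approximation of k when m*n exceeds ``exact_max_pairs``).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    m, n = x.size, y.size
    diffs = np.sort((y[None, :] - x[:, None]).ravel())
    est = float(np.median(diffs))
    mn = m * n
    if mn <= exact_max_pairs:
        counts = _mann_whitney_counts(m, n)
        cdf = np.cumsum(counts) / math.comb(m + n, m)
        below = np.nonzero(cdf <= alpha / 2)[0]
        k = int(below[-1]) if below.size else -1
        method = "hodges-lehmann, exact mann-whitney inversion CI"
    else:
        z = sps.norm.ppf(alpha / 2)
        k = int(math.floor(mn / 2 + z * math.sqrt(mn * (m + n + 1) / 12.0)))
        k = max(-1, min(k, mn // 2 - 1))
        method = "hodges-lehmann, normal-approximation inversion CI"
    if k < 0:
        lo, hi = float(diffs[0]), float(diffs[-1])
    else:
        # 1-based [D_(k+1), D_(mn-k)]
        lo, hi = float(diffs[k]), float(diffs[mn - 1 - k])
    lo, hi = min(lo, est), max(hi, est)
    return StatResult(method=method, estimate=est, ci_low=lo, ci_high=hi)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient for paired samples.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2) with population
    (1/n) moments; 1 means perfect agreement, and |CCC| <= |Pearson r|.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d samples")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    mx, my = x.mean(), y.mean()
    sxy = np.mean((x - mx) * (y - my))
    denom = x.var() + y.var() + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: both samples constant and equal")
    return float(2.0 * sxy / denom)


def bootstrap_ci(statistic, data, n_resamples: int = 2000,
                 seed: int | None = None, alpha: float = 0.05,
                 max_failure_fraction: float = 0.10):
    """Percentile bootstrap CI for a statistic of paired columns.

    ``data`` is a sequence of equal-length arrays resampled case-wise
    (rows drawn together with replacement); ``statistic`` receives the
    resampled columns as positional arguments.  Resamples on which the
    statistic raises or returns NaN are dropped; more than
    ``max_failure_fraction`` failures is an error.  Fully reproducible
    given ``seed``.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    cols = [np.asarray(c) for c in data]
    n = cols[0].shape[0]
    if any(c.shape[0] != n for c in cols):
        raise ValueError("all data columns must have equal length")
    rng = np.random.default_rng(seed)
    values = []
    failures = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        try:
            v = statistic(*(c[idx] for c in cols))
        except (ValueError, ZeroDivisionError, FloatingPointError):
            failures += 1
            continue
        if v is None or (isinstance(v, float) and math.isnan(v)):
            failures += 1
            continue
        values.append(v)
    if failures > max_failure_fraction * n_resamples:
        raise ValueError(f"statistic undefined on {failures}/{n_resamples} "
                         "bootstrap resamples")
    values = np.asarray(values, float)
    lo = float(np.percentile(values, 100 * alpha / 2))
    hi = float(np.percentile(values, 100 * (1 - alpha / 2)))
    return lo, hi


def lin_ccc_with_ci(x, y, n_resamples: int = 2000,
                    seed: int | None = None) -> StatResult:
    """Plug-in CCC with a seeded percentile-bootstrap 95% CI."""
    est = lin_ccc(x, y)
    lo, hi = bootstrap_ci(lin_ccc, (x, y), n_resamples=n_resamples, seed=seed)
    return StatResult(method="lin CCC, percentile bootstrap CI",
                      estimate=est, ci_low=min(lo, est), ci_high=max(hi, est),
                      n_resamples=n_resamples, seed=seed)


def median_iqr(x):
    """Median and quartiles (q1, q3) of a non-empty sample.

    Quartiles use the SAS empirical-distribution-with-averaging rule
    (numpy ``averaged_inverted_cdf``), which e.g. gives IQR (6, 8) for
    {6,6,7,7,7,8,8}.
    """
    x = np.asarray(x, float)
    if x.size == 0:
        raise ValueError("empty sample")
    q1 = float(np.quantile(x, 0.25, method=QUANTILE_METHOD))
    q3 = float(np.quantile(x, 0.75, method=QUANTILE_METHOD))
    return float(np.median(x)), q1, q3
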