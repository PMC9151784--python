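"""Statistical kernel shared by all pipeline stages.

Exact hypergeometric upper tails (log-factorial arithmetic), Student-t
two-sided tails, Benjamini–Hochberg step-up adjustment, Pearson correlation
with OLS regression, and row Z-scores for expression heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, gammaln

__all__ = [
    "HypergeomTest",
    "CorrelationReport",
    "hypergeom_tail",
    "bh_adjust",
    "student_t_tail",
    "pearson_regression",
    "row_zscore",
]


@dataclass
class HypergeomTest:
    """One scaffold-pair enrichment test.

    Drawing ``draws_n`` anchors from a population of ``population_N`` of which
    ``successes_K`` lie on the row scaffold; ``observed_k`` landed in the cell.
    """

    population_N: int
    successes_K: int
    draws_n: int
    observed_k: int
    p_one_tailed: float
    q_bh: float | None = None


@dataclass
class CorrelationReport:
    """Pearson correlation plus the OLS line through the same points."""

    n: int
    r: float
    t_stat: float
    df: int
    p_two_sided: float
    slope: float
    intercept: float


def _log_binom(n: float, k: np.ndarray | float) -> np.ndarray | float:
    return gammaln(n + 1) - gammaln(np.asarray(k) + 1) - gammaln(n - np.asarray(k) + 1)


def hypergeom_tail(population_N: int, successes_K: int, draws_n: int, observed_k: int) -> float:
    """Upper tail P(X >= observed_k) of Hypergeometric(N, K, n).

    Computed as an exact sum of probabilities in log space (no normal
    approximation); this is the one-tailed enrichment test used for
    scaffold-pair ortholog counts.
    """
    N, K, n, k = population_N, successes_K, draws_n, observed_k
    if min(N, K, n) < 0:
        raise ValueError("counts must be non-negative")
    if K > N or n > N:
        raise ValueError("successes_K and draws_n cannot exceed population_N")
    hi = min(K, n)
    lo = max(0, n - (N - K))
    if k > hi:
        return 0.0
    if k <= lo:
        return 1.0
    support = np.arange(k, hi + 1)
    logp = _log_binom(K, support) + _log_binom(N - K, n - support) - _log_binom(N, n)
    # log-sum-exp keeps the tail exact to double precision even at N ~ 1e4
    m = logp.max()
    return float(min(1.0, np.exp(m) * np.exp(logp - m).sum()))


def bh_adjust(pvalues) -> list[float]:
    """Benjamini–Hochberg step-up q-values, returned in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def student_t_tail(t: float, df: int) -> float:
    """Two-sided tail P(|T| >= |t|) for Student's t with ``df`` degrees of freedom.

    Uses the regularized incomplete beta identity
    P(|T| >= |t|) = I_{df/(df+t^2)}(df/2, 1/2).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = float(t)
    if t == 0.0:
        return 1.0
    x = df / (df + t * t)
    return float(betainc(df / 2.0, 0.5, x))


def pearson_regression(x, y) -> CorrelationReport:
    """Pearson product-moment correlation with its t test and the OLS fit.

    The t statistic is r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom; the
    slope and intercept are the least-squares line of y on x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("x is constant")
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy == 0.0:
        # y constant: perfectly fit by the horizontal line, correlation undefined;
        # report r = 0 with p = 1
        return CorrelationReport(n, 0.0, 0.0, n - 2, 1.0, slope, intercept)
    r = sxy / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        t_stat = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        t_stat = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = student_t_tail(t_stat, n - 2)
    return CorrelationReport(n, r, float(t_stat), n - 2, float(p), float(slope), intercept)


def row_zscore(matrix) -> np.ndarray:
    """Z-score each row: centre by the row mean, scale by the sample (n-1) SD.

    Zero-variance rows map to all-zero rows, the usual heatmap convention.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 columns")
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (m - mu) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return z
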