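"""Shared statistical primitives used by every analysis layer.

Multiple-testing correction (Benjamini–Hochberg step-up), rank statistics
(Spearman's rho, Wilcoxon signed-rank and rank-sum with exact small-sample
null distributions), and empirical-Bayes variance moderation for the
probe-/gene-wise two-group tests.

All functions are pure and operate on plain numpy arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats as sps

__all__ = [
    "PValueVector",
    "RankTestResult",
    "ModeratedVariance",
    "bh_adjust",
    "spearman_rho",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "moderate_variances",
]

# Exact null enumeration is used up to these sample sizes; beyond them the
# normal approximation (with tie and continuity corrections) takes over.
SIGNED_RANK_EXACT_MAX = 25
RANK_SUM_EXACT_MAX = 10


@dataclass
class PValueVector:
    """Raw and BH-adjusted p-values, input order preserved."""

    p: np.ndarray
    p_adj: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.p_adj = np.asarray(self.p_adj, dtype=float)


@dataclass
class RankTestResult:
    """Outcome of a Wilcoxon-type rank test.

    ``statistic`` is the signed-rank W (sum of positive ranks) or the
    Mann-Whitney U of the first sample.  ``method`` records whether the
    null distribution was enumerated exactly or approximated.
    """

    statistic: float
    p: float
    sidedness: str
    method: str
    degenerate: bool = False


@dataclass
class ModeratedVariance:
    """Per-unit variances shrunken toward a common prior (Smyth-style)."""

    s2: np.ndarray
    d: float
    d0: float
    s0_2: float
    s2_post: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.s2 = np.asarray(self.s2, dtype=float)
        if np.isinf(self.d0):
            self.s2_post = np.full_like(self.s2, self.s0_2)
        else:
            self.s2_post = (self.d0 * self.s0_2 + self.d * self.s2) / (self.d0 + self.d)

    @property
    def df_total(self) -> float:
        """Total degrees of freedom of the moderated statistic.

        Complete shrinkage (d0 = inf) pins every posterior variance at the
        prior, so the statistic has unbounded degrees of freedom.
        """
        return np.inf if np.isinf(self.d0) else self.d + self.d0


def bh_adjust(p, m: int | None = None) -> PValueVector:
    """Benjamini–Hochberg step-up adjusted p-values.

    Parameters
    ----------
    p : array-like
        Raw p-values in [0, 1].
    m : int, optional
        Total number of tests; defaults to ``len(p)`` and must be at least
        that.  Allows adjusting a subset while accounting for all tests.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"m={m} is smaller than the number of p-values ({n})")
    if n == 0:
        return PValueVector(p=p, p_adj=p.copy())
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    p_adj = np.empty(n, dtype=float)
    p_adj[order] = adj
    return PValueVector(p=p, p_adj=p_adj)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def _signed_rank_exact_sf(w: float, ranks: np.ndarray) -> float:
    """P(W >= w) by dynamic programming over all 2^n sign assignments.

    Ranks are scaled to integers (ties give half-integer average ranks, so
    doubling makes them integral); the null distribution of the doubled
    statistic is built by polynomial convolution.
    """
    r2 = np.round(ranks * 2).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(np.round(w * 2))
    return float(dist[w2:].sum())


def wilcoxon_signed_rank(x, y=None, sidedness: str = "two-sided") -> RankTestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (the classical convention); ties among
    the remaining absolute differences receive average ranks.  For at most
    ``SIGNED_RANK_EXACT_MAX`` nonzero pairs the exact null distribution of
    W (sum of positive ranks) is enumerated; otherwise a normal
    approximation with tie and continuity corrections is used.

    ``sidedness='greater'`` tests whether x tends to exceed y.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if sidedness not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p set to 1", UserWarning)
        return RankTestResult(0.0, 1.0, sidedness, "degenerate", degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    w_total = float(ranks.sum())
    if n <= SIGNED_RANK_EXACT_MAX:
        sf = _signed_rank_exact_sf(w, ranks)  # P(W >= w)
        cdf = 1.0 - _signed_rank_exact_sf(w + 0.5, ranks)  # P(W <= w)
        if sidedness == "greater":
            p = sf
        elif sidedness == "less":
            p = cdf
        else:
            p = min(1.0, 2.0 * min(sf, cdf))
        return RankTestResult(w, p, sidedness, "exact")
    mu = w_total / 2.0
    # variance with tie correction: sum r_i^2 / 4
    sigma2 = float((ranks**2).sum()) / 4.0
    sigma = np.sqrt(sigma2)
    if sidedness == "greater":
        z = (w - mu - 0.5) / sigma
        p = float(sps.norm.sf(z))
    elif sidedness == "less":
        z = (w - mu + 0.5) / sigma
        p = float(sps.norm.cdf(z))
    else:
        z = (abs(w - mu) - 0.5) / sigma
        p = float(2.0 * sps.norm.sf(z))
    return RankTestResult(w, min(p, 1.0), sidedness, "normal-approximation")


def _rank_sum_null_counts(n: int, m: int) -> np.ndarray:
    """Exact null counts of the Mann-Whitney U for sample sizes (n, m).

    Entry u holds the number of rank assignments with U = u; these are the
    coefficients of the Gaussian binomial [n+m choose n]_q, built by exact
    integer polynomial multiplication/division of
    prod_{i=1..n} (1 - q^{m+i}) / (1 - q^i).
    """
    coeffs = [1]
    for i in range(1, n + 1):
        # multiply by (1 - q^{m+i})
        deg = len(coeffs) - 1 + m + i
        prod = [0] * (deg + 1)
        for j, c in enumerate(coeffs):
            prod[j] += c
            prod[j + m + i] -= c
        # divide by (1 - q^i): b[j] = a[j] + b[j-i]
        for j in range(i, len(prod)):
            prod[j] += prod[j - i]
        # exact division leaves trailing zeros; trim to degree n*... keep all
        while prod and prod[-1] == 0:
            prod.pop()
        coeffs = prod
    return np.asarray(coeffs, dtype=float)


def _rank_sum_exact_sf(u: float, n: int, m: int) -> float:
    """P(U >= u) under the exact Mann-Whitney null (no ties)."""
    counts = _rank_sum_null_counts(n, m)
    dist = counts / counts.sum()
    u_int = int(np.ceil(u - 1e-9))
    u_int = max(u_int, 0)
    return float(dist[u_int:].sum()) if u_int < dist.size else 0.0


def wilcoxon_rank_sum(x, y, sidedness: str = "two-sided") -> RankTestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    U is the Mann-Whitney statistic of ``x``.  Exact enumeration when
    ``min(n, m) <= RANK_SUM_EXACT_MAX`` and the data carry no ties,
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if sidedness not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r_x = float(ranks[:n].sum())
    u = r_x - n * (n + 1) / 2.0
    has_ties = np.unique(combined).size < combined.size
    if min(n, m) <= RANK_SUM_EXACT_MAX and not has_ties:
        sf = _rank_sum_exact_sf(u, n, m)  # P(U >= u)
        cdf = 1.0 - _rank_sum_exact_sf(u + 0.5, n, m)
        if sidedness == "greater":
            p = sf
        elif sidedness == "less":
            p = cdf
        else:
            p = min(1.0, 2.0 * min(sf, cdf))
        return RankTestResult(u, p, sidedness, "exact")
    mu = n * m / 2.0
    nm = n + m
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    sigma2 = n * m / 12.0 * (nm + 1 - tie_term / (nm * (nm - 1)))
    sigma = np.sqrt(max(sigma2, 1e-300))
    if sidedness == "greater":
        z = (u - mu - 0.5) / sigma
        p = float(sps.norm.sf(z))
    elif sidedness == "less":
        z = (u - mu + 0.5) / sigma
        p = float(sps.norm.cdf(z))
    else:
        z = (abs(u - mu) - 0.5) / sigma
        p = float(2.0 * sps.norm.sf(z))
    return RankTestResult(u, min(p, 1.0), sidedness, "normal-approximation")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(s2, d: float) -> ModeratedVariance:
    """Empirical-Bayes shrinkage of per-unit sample variances.

    Fits a scaled inverse chi-square prior (d0, s0^2) to the observed
    variances by method of moments on log(s2) and returns the posterior
    variances ``(d0*s0^2 + d*s2) / (d0 + d)``.  With fewer than 10 units
    no shrinkage is attempted (d0 = 0).
    """
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 < 0):
        raise ValueError("variances must be non-negative")
    if d < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    n = s2.size
    if n < 10:
        warnings.warn("fewer than 10 units: skipping shrinkage (d0=0)", UserWarning)
        return ModeratedVariance(s2=s2, d=d, d0=0.0, s0_2=float(np.mean(s2)) if n else 1.0)
    # work on log scale; guard exact zeros
    s2_safe = np.maximum(s2, 1e-300)
    z = np.log(s2_safe)
    if np.ptp(z) == 0:
        # literally identical variances: point-mass prior at the common value
        return ModeratedVariance(s2=s2, d=float(d), d0=np.inf, s0_2=float(s2_safe[0]))
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) * (n - 1) / n - float(special.polygamma(1, d / 2.0))
    if e_var <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModeratedVariance(s2=s2, d=float(d), d0=float(d0), s0_2=s0_2)
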