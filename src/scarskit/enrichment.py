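"""Overlap-enrichment statistics: hypergeometric tests, Fisher's exact test,
chi-square, the combined score, and multiple-testing adjustment.

The central object is the overlap quadruple ``(N, K, n, k)``: a background of
``N`` genes of which ``K`` carry some property, a query set of ``n`` genes,
and ``k`` genes in common.  Under the null that the query is a uniform draw,
``k`` is hypergeometric; the test reports

* ``expected = n*K/N`` and the observed/expected ratio ``k/expected``;
* ``p`` — the upper tail ``P(X >= k)``, summed in log space so values at the
  1e-300 scale remain representable;
* ``p_point`` — the point probability ``P(X = k)``.  Published enrichment
  tables in this domain are frequently produced with spreadsheet-style
  non-cumulative hypergeometric calls, so the point probability is the value
  needed to reproduce such printed tables digit-for-digit; the upper tail is
  the statistically preferred test and is what ranking and adjustment use.
* the "analytic combined score" ``c = ln(p) * z`` with ``z`` the analytic
  z-score of the overlap count ``(k - expected)/sd`` under the hypergeometric
  null (rather than a rank-permutation z).

All hypergeometric and Fisher probabilities are computed from log-factorials
(:func:`scipy.special.gammaln`); no probability is formed by subtracting
near-equal CDF values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2 as _chi2_dist
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetLibrary

__all__ = [
    "OverlapParams",
    "EnrichmentResult",
    "ContingencyTable2x2",
    "hypergeom_logpmf",
    "hypergeom_sf",
    "hypergeom_overlap_test",
    "fisher_exact_two_tailed",
    "chi_square_test",
    "combined_score",
    "adjust_pvalues",
    "gene_set_enrichment",
]


@dataclass(frozen=True)
class OverlapParams:
    """The hypergeometric overlap quadruple.

    N : background (population) size, e.g. all annotated genes.
    K : background members carrying the property (population successes).
    n : query-set size (sample size).
    k : observed overlap.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N):
            raise ValueError(f"K={self.K} must satisfy 0 <= K <= N={self.N}")
        if not (0 <= self.n <= self.N):
            raise ValueError(f"n={self.n} must satisfy 0 <= n <= N={self.N}")
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(
                f"k={self.k} must satisfy 0 <= k <= min(n={self.n}, K={self.K})"
            )
        if self.k < self.n + self.K - self.N:
            raise ValueError(
                f"k={self.k} below the hypergeometric support floor "
                f"max(0, n+K-N)={self.n + self.K - self.N}"
            )

    @property
    def expected(self) -> float:
        return self.n * self.K / self.N

    @property
    def variance(self) -> float:
        if self.N <= 1:
            return 0.0
        p = self.K / self.N
        return self.n * p * (1.0 - p) * (self.N - self.n) / (self.N - 1)


@dataclass
class EnrichmentResult:
    """The printed-statistic bundle for one overlap test."""

    params: OverlapParams
    expected: float
    oe_ratio: float | None
    p: float
    p_point: float
    combined: float | None
    set_name: str = ""
    p_adjusted: float | None = None
    log_p: float = 0.0  # natural-log upper tail; finite even where p underflows


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts ``[[a, b], [c, d]]`` of a 2x2 contingency table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValueError(f"negative count in {counts}")
        if all(x == 0 for x in counts):
            raise ValueError("all-zero contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


# ---------------------------------------------------------------------------
# Hypergeometric core (log-space)
# ---------------------------------------------------------------------------


def _log_binom(n: float, k: float) -> float:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def hypergeom_logpmf(k: int, N: int, K: int, n: int) -> float:
    """``log P(X = k)`` for X ~ Hypergeometric(N, K, n); ``-inf`` off support."""
    if k < max(0, n + K - N) or k > min(n, K):
        return -math.inf
    return _log_binom(K, k) + _log_binom(N - K, n - k) - _log_binom(N, n)


def hypergeom_logsf(k: int, N: int, K: int, n: int) -> float:
    """``log P(X >= k)`` (inclusive upper tail), summed in log space, so
    tails far below float underflow remain representable on the log scale."""
    hi = min(n, K)
    if k > hi:
        return -math.inf
    if k <= max(0, n + K - N):
        return 0.0
    ks = np.arange(k, hi + 1)
    logs = (
        _log_binom(K, ks)
        + _log_binom(N - K, n - ks)
        - _log_binom(N, n)
    )
    return float(min(0.0, logsumexp(logs)))


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Inclusive upper tail ``P(X >= k)``; exact to the 1e-300 scale."""
    return math.exp(hypergeom_logsf(k, N, K, n))


def hypergeom_overlap_test(
    params: OverlapParams, set_name: str = ""
) -> EnrichmentResult:
    """Upper-tail hypergeometric overlap test with O/E ratio and combined score.

    The O/E ratio is undefined (``None``) when ``K = 0`` or ``n = 0``; a
    positive overlap is then impossible and ``k > 0`` raises on construction
    of :class:`OverlapParams`.
    """
    N, K, n, k = params.N, params.K, params.n, params.k
    log_p = hypergeom_logsf(k, N, K, n)
    p_point = math.exp(hypergeom_logpmf(k, N, K, n))
    expected = params.expected
    oe = k / expected if expected > 0 else None
    # combined score straight from the log tail: no underflow round-trip
    var = params.variance
    c = log_p * (k - expected) / math.sqrt(var) if var > 0 else None
    return EnrichmentResult(
        params=params,
        expected=expected,
        oe_ratio=oe,
        p=math.exp(log_p),
        log_p=log_p,
        p_point=p_point,
        combined=c,
        set_name=set_name,
    )


def combined_score(p: float, params: OverlapParams) -> float | None:
    """Analytic combined score ``c = ln(p) * z``.

    ``z = (k - expected)/sd`` under the hypergeometric null.  Pairs the
    significance estimate with the magnitude of enrichment; reported alongside
    ``p``, never replacing it.  Returns ``None`` when the null variance is
    zero (degenerate overlap problem).
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p={p} outside (0, 1]")
    var = params.variance
    if var <= 0.0:
        return None
    z = (params.k - params.expected) / math.sqrt(var)
    return math.log(p) * z


# ---------------------------------------------------------------------------
# Fisher's exact test (two-tailed, full enumeration)
# ---------------------------------------------------------------------------

_TWO_TAIL_SLACK = 1.0 + 1e-7  # relative tie tolerance when summing the other tail


def fisher_exact_two_tailed(table: ContingencyTable2x2) -> float:
    """Two-tailed Fisher's exact p by summation over the conditional support.

    With margins fixed, the table is indexed by its ``a`` cell, which is
    hypergeometric.  The two-tailed p sums the probabilities of every table
    whose point probability does not exceed the observed one (within a 1e-7
    relative tie tolerance, the convention used by mainstream
    implementations).  Degenerate margins give p = 1 with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    N = table.total
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == N or c1 == N:
        warnings.warn("degenerate margin in 2x2 table; Fisher p = 1", stacklevel=2)
        return 1.0
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = (
        _log_binom(c1, support)
        + _log_binom(N - c1, r1 - support)
        - _log_binom(N, r1)
    )
    log_obs = logp[a - lo]
    keep = logp <= log_obs + math.log(_TWO_TAIL_SLACK)
    return float(min(1.0, math.exp(logsumexp(logp[keep]))))


def chi_square_test(table: ContingencyTable2x2, correction: bool = False) -> float:
    """Pearson chi-square p (1 df) for a 2x2 table; optional Yates correction.

    Raises when any expected cell is zero (a degenerate margin) and points the
    caller to Fisher's exact test instead.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    N = table.total
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError(
            "zero expected cell (degenerate margin); use fisher_exact_two_tailed"
        )
    diff = abs(a * d - b * c)
    if correction:
        diff = max(0.0, diff - N / 2.0)
    stat = N * diff**2 / (r1 * r2 * c1 * c2)
    return float(_chi2_dist.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Multiple-testing adjustment
# ---------------------------------------------------------------------------


def adjust_pvalues(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """Adjust p values; ``method`` is ``"bonferroni"`` or ``"bh"`` (step-up FDR).

    Input order is preserved.  Delegates to
    :func:`statsmodels.stats.multitest.multipletests`.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


# ---------------------------------------------------------------------------
# Library-wide enrichment
# ---------------------------------------------------------------------------


def gene_set_enrichment(
    query: Iterable[str],
    library: GeneSetLibrary,
    background: Iterable[str],
    adjust: str = "bh",
) -> list[EnrichmentResult]:
    """Test a query gene set against every set in a library.

    Each library set is intersected with the background before testing, with
    ``N = |background|``, ``K = |set ∩ background|``, ``n = |query|`` and
    ``k = |query ∩ set|``.  Results are BH-adjusted by default and sorted by
    upper-tail p ascending, ties broken lexicographically by set name.
    """
    query_set = set(query)
    background_set = set(background)
    if not query_set or not background_set:
        raise ValueError("query and background must be non-empty")
    if not query_set <= background_set:
        missing = sorted(query_set - background_set)[:5]
        raise ValueError(f"query genes outside the background, e.g. {missing}")
    N, n = len(background_set), len(query_set)
    results = []
    for name, (_desc, members) in library.items():
        hits = set(members) & background_set
        params = OverlapParams(N=N, K=len(hits), n=n, k=len(query_set & hits))
        results.append(hypergeom_overlap_test(params, set_name=name))
    adjusted = adjust_pvalues([r.p for r in results], method=adjust)
    for r, q in zip(results, adjusted):
        r.p_adjusted = float(q)
    results.sort(key=lambda r: (r.p, r.set_name))
    return results
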