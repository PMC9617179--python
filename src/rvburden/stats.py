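"""Stratified and unstratified exact association tests for 2x2 carrier tables.

The central object is a :class:`StratifiedTable`: one 2x2 table
(case/control x carrier/non-carrier) per ancestry cluster. Effect sizes are
pooled with the Mantel-Haenszel estimator and a Robins-Breslow-Greenland
(RBG) Wald interval on the log odds ratio; significance comes from the exact
conditional Cochran-Mantel-Haenszel (CMH) test, whose null distribution of
the total case-carrier count is the convolution of per-stratum central
hypergeometric distributions given the margins.

Conventions (documented, switchable where the field has no single standard):

* exact CMH two-sided p: doubled smaller tail, capped at 1;
* Fisher two-sided p: point-probability method (sum of tables no more
  probable than the observed one);
* no continuity corrections anywhere; zero-margin strata are dropped from
  both estimation and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StratifiedTable",
    "CMHResult",
    "FisherResult",
    "mh_pooled_odds_ratio",
    "cmh_exact_test",
    "cmh_asymptotic_test",
    "fisher_exact_test",
    "genomic_inflation_lambda",
    "bonferroni_alpha",
    "bh_adjust",
]

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN = float(sps.chi2.ppf(0.5, df=1))


@dataclass(frozen=True)
class StratifiedTable:
    """Per-cluster 2x2 counts for one gene or gene set.

    Stratum ``k`` holds ``a[k]`` case carriers, ``b[k]`` case non-carriers,
    ``c[k]`` control carriers and ``d[k]`` control non-carriers.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    clusters: tuple = ()

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if (arr < 0).any():
                raise ValueError(f"negative count in stratum column {name!r}")
            object.__setattr__(self, name, arr)
        if not (self.a.shape == self.b.shape == self.c.shape == self.d.shape):
            raise ValueError("stratum count arrays must have equal length")
        if not self.clusters:
            object.__setattr__(self, "clusters", tuple(range(len(self.a))))

    @property
    def n_strata(self) -> int:
        return len(self.a)

    @property
    def n(self) -> np.ndarray:
        """Total individuals per stratum."""
        return self.a + self.b + self.c + self.d

    def informative(self) -> "StratifiedTable":
        """Drop strata with a zero margin (no cases, no controls, no
        carriers, or no non-carriers); such strata contribute nothing to
        either the MH estimator or the conditional null distribution."""
        m1 = self.a + self.c
        m0 = self.b + self.d
        n1 = self.a + self.b
        n0 = self.c + self.d
        keep = (m1 > 0) & (m0 > 0) & (n1 > 0) & (n0 > 0)
        return StratifiedTable(
            self.a[keep], self.b[keep], self.c[keep], self.d[keep],
            tuple(cl for cl, k in zip(self.clusters, keep) if k),
        )

    @staticmethod
    def single(a: int, b: int, c: int, d: int) -> "StratifiedTable":
        return StratifiedTable(np.array([a]), np.array([b]), np.array([c]), np.array([d]))


@dataclass(frozen=True)
class CMHResult:
    pooled_or: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    table: StratifiedTable = field(repr=False, default=None)
    degenerate: bool = False


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Mantel-Haenszel pooled odds ratio and RBG confidence interval
# ---------------------------------------------------------------------------

def mh_pooled_odds_ratio(table: StratifiedTable, alpha: float = 0.05):
    """Mantel-Haenszel pooled odds ratio with a Wald interval on the log
    scale using the Robins-Breslow-Greenland variance.

    Returns ``(or, ci_low, ci_high)``. A zero MH denominator yields
    ``inf`` with NaN bounds (flagged by the caller via non-finiteness).
    """
    t = table.informative()
    if t.n_strata == 0:
        raise ValueError("no informative stratum: every 2x2 has a zero margin")
    n = t.n.astype(float)
    R = t.a * t.d / n
    S = t.b * t.c / n
    sum_r, sum_s = R.sum(), S.sum()
    if sum_s == 0:
        return np.inf, np.nan, np.nan
    if sum_r == 0:
        return 0.0, np.nan, np.nan
    or_mh = sum_r / sum_s
    P = (t.a + t.d) / n
    Q = (t.b + t.c) / n
    var_log = (
        (P * R).sum() / (2 * sum_r**2)
        + ((P * S + Q * R).sum()) / (2 * sum_r * sum_s)
        + (Q * S).sum() / (2 * sum_s**2)
    )
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var_log)
    log_or = np.log(or_mh)
    return float(or_mh), float(np.exp(log_or - half)), float(np.exp(log_or + half))


# ---------------------------------------------------------------------------
# Exact conditional CMH test
# ---------------------------------------------------------------------------

def _stratum_support(N: int, m1: int, n1: int):
    """Support and pmf of the central hypergeometric count of case carriers
    in a stratum with ``N`` individuals, ``m1`` carriers, ``n1`` cases."""
    lo = max(0, n1 + m1 - N)
    hi = min(n1, m1)
    ks = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(ks, N, m1, n1)
    return lo, pmf


def cmh_null_distribution(table: StratifiedTable):
    """Null distribution of S = sum of case-carrier counts across strata.

    Returns ``(offset, pmf)`` where ``pmf[i]`` is P(S = offset + i) under
    the conditional null of common OR = 1. Computed by dynamic-programming
    convolution of per-stratum central hypergeometric pmfs — exact for the
    stratum counts arising in cohort-scale collapsing analyses.
    """
    offset = 0
    dist = np.array([1.0])
    for a, b, c, d in zip(table.a, table.b, table.c, table.d):
        N = a + b + c + d
        m1 = a + c
        n1 = a + b
        if N == 0 or m1 == 0 or m1 == N or n1 == 0 or n1 == N:
            # degenerate hypergeometric: point mass at the forced count
            offset += min(n1, m1)
            continue
        lo, pmf = _stratum_support(N, m1, n1)
        offset += lo
        dist = np.convolve(dist, pmf)
    # guard against tiny negative values from floating-point convolution
    np.clip(dist, 0.0, None, out=dist)
    return offset, dist


def cmh_exact_test(table: StratifiedTable, alpha: float = 0.05) -> CMHResult:
    """Exact conditional test of common odds ratio = 1 across strata.

    Two-sided p is the doubled smaller tail of the convolved hypergeometric
    distribution of S = sum of case carriers, capped at 1. Strata with a
    zero margin are dropped; a table with no informative stratum is
    degenerate and returns p = 1 with an undefined OR.
    """
    t = table.informative()
    if t.n_strata == 0:
        return CMHResult(np.nan, np.nan, np.nan, 1.0, table, degenerate=True)
    s_obs = int(t.a.sum())
    offset, dist = cmh_null_distribution(t)
    idx = s_obs - offset
    p_le = float(dist[: idx + 1].sum())
    p_ge = float(dist[idx:].sum())
    p = min(1.0, 2.0 * min(p_le, p_ge))
    p = max(p, float(dist[idx]))  # never below the point probability
    or_mh, lo, hi = mh_pooled_odds_ratio(t, alpha=alpha)
    return CMHResult(or_mh, lo, hi, p, table)


def cmh_asymptotic_test(table: StratifiedTable, alpha: float = 0.05) -> CMHResult:
    """Asymptotic CMH chi-square test (1 df, no continuity correction).

    Used inside permutation loops where the exact convolution would be
    recomputed hundreds of thousands of times; agrees with the exact test
    at the carrier counts typical of cohort-scale gene sets.
    """
    t = table.informative()
    if t.n_strata == 0:
        return CMHResult(np.nan, np.nan, np.nan, 1.0, table, degenerate=True)
    n = t.n.astype(float)
    m1 = (t.a + t.c).astype(float)
    m0 = (t.b + t.d).astype(float)
    n1 = (t.a + t.b).astype(float)
    n0 = (t.c + t.d).astype(float)
    expect = (n1 * m1 / n).sum()
    var = (n1 * n0 * m1 * m0 / (n**2 * (n - 1))).sum()
    if var == 0:
        return CMHResult(np.nan, np.nan, np.nan, 1.0, table, degenerate=True)
    stat = (t.a.sum() - expect) ** 2 / var
    p = float(sps.chi2.sf(stat, df=1))
    or_mh, lo, hi = mh_pooled_odds_ratio(t, alpha=alpha)
    return CMHResult(or_mh, lo, hi, max(p, np.finfo(float).tiny), table)


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def fisher_exact_test(a: int, b: int, c: int, d: int, alpha: float = 0.05) -> FisherResult:
    """Two-sided Fisher exact test on a single 2x2 table.

    p sums hypergeometric point probabilities no larger than that of the
    observed table (the point-probability method). The reported odds ratio
    is the conditional sample OR ``ad/bc``; a zero cell makes it 0 or inf
    and flags the result. The CI is the conditional exact (Cornfield)
    interval.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        return FisherResult(np.nan, np.nan, np.nan, 1.0, degenerate=True)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        or_ = np.inf if a * d > 0 else np.nan
        degenerate = True
    else:
        or_ = a * d / (b * c)
        degenerate = or_ == 0.0
    ci = _conditional_odds_ratio([[a, b], [c, d]]).confidence_interval(1 - alpha)
    return FisherResult(float(or_), float(ci.low), float(ci.high), float(p), degenerate)


# ---------------------------------------------------------------------------
# Diagnostics and multiplicity corrections
# ---------------------------------------------------------------------------

def genomic_inflation_lambda(p_values) -> float:
    """Genomic inflation factor: median chi-square(1 df) quantile of the
    observed p-values over the null chi-square(1) median (0.4549)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("genomic_inflation_lambda requires at least one p-value")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = sps.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m for m comparisons."""
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    return alpha / m


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1,
    returned in the input order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
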