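"""Statistical kernels with exact small-sample behavior.

Cohen's kappa, Spearman rank correlation, Mann-Whitney U, Wilcoxon
signed-rank and simple linear regression with a slope-difference test.
The rank tests enumerate their exact null distributions at small n
(sign patterns for Wilcoxon, group assignments for Mann-Whitney) so that
small-cohort p-values are reproducible as counts; larger samples fall back
to the tie-corrected normal approximation from scipy.  All p-values are
two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from scipy import stats as sps

#: largest per-group size for which Mann-Whitney enumerates all assignments
MW_EXACT_MAX_N = 10
#: largest number of nonzero pairs for which Wilcoxon enumerates sign patterns
WILCOXON_EXACT_MAX_N = 12


@dataclass(frozen=True)
class AgreementTable:
    """2x2 agreement counts: a=both+, b=rater1+ only, c=rater2+ only, d=both-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be non-negative")
        if self.total == 0:
            raise ValueError("agreement table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_labels(cls, r1, r2) -> "AgreementTable":
        r1 = np.asarray(r1, bool)
        r2 = np.asarray(r2, bool)
        return cls(int(np.sum(r1 & r2)), int(np.sum(r1 & ~r2)),
                   int(np.sum(~r1 & r2)), int(np.sum(~r1 & ~r2)))


def cohens_kappa(table: AgreementTable) -> float:
    """Chance-corrected agreement ``(po - pe) / (1 - pe)``.

    ``po`` is the observed agreement proportion and ``pe`` the agreement
    expected from the marginal positive rates of the two raters.  Returns
    NaN when ``pe == 1`` (both raters constant), where kappa is undefined.
    """
    n = table.total
    po = (table.a + table.d) / n
    pe = ((table.a + table.b) * (table.a + table.c)
          + (table.c + table.d) * (table.b + table.d)) / n**2
    if pe >= 1.0 - 1e-15:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def spearman(x, y) -> float:
    """Spearman correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks.  Returns NaN if either variable has zero
    rank variance (all values tied).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("spearman needs n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def _two_sided_from_tails(lo: float, hi: float) -> float:
    return float(min(1.0, 2.0 * min(lo, hi)))


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U test; returns ``(U, p)`` with U counted for ``x``.

    Exact p by full enumeration of the C(n+m, n) group assignments of the
    pooled mid-ranks when both groups have <= 10 observations; otherwise the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    ranks = sps.rankdata(np.concatenate([x, y]))
    r_x = float(ranks[:n].sum())
    u_x = r_x - n * (n + 1) / 2.0

    if n <= MW_EXACT_MAX_N and m <= MW_EXACT_MAX_N:
        total = math.comb(n + m, n)
        lo = hi = 0
        for idx in combinations(range(n + m), n):
            u = ranks[list(idx)].sum() - n * (n + 1) / 2.0
            if u <= u_x + 1e-9:
                lo += 1
            if u >= u_x - 1e-9:
                hi += 1
        p = _two_sided_from_tails(lo / total, hi / total)
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
        p = float(res.pvalue)
    return u_x, p


def wilcoxon_signed_rank(diffs) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences; returns ``(W, p)``.

    Zero differences are dropped.  W is the positive-rank sum.  For <= 12
    nonzero pairs the exact two-sided p is computed by enumerating all 2^n
    sign patterns over the mid-ranked |differences|; larger samples use the
    normal approximation.  Raises ValueError if every difference is zero
    (the statistic is undefined).
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero: test undefined")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())

    if n <= WILCOXON_EXACT_MAX_N:
        total = 2**n
        lo = hi = 0
        for signs in product((0, 1), repeat=n):
            ws = float(np.dot(signs, ranks))
            if ws <= w + 1e-9:
                lo += 1
            if ws >= w - 1e-9:
                hi += 1
        p = _two_sided_from_tails(lo / total, hi / total)
    else:
        res = sps.wilcoxon(d, alternative="two-sided", method="approx",
                           correction=True)
        p = float(res.pvalue)
    return w, p


@dataclass(frozen=True)
class RegressionComparison:
    slope_a: float
    intercept_a: float
    r2_a: float
    slope_b: float
    intercept_b: float
    r2_b: float
    slope_diff: float
    slope_diff_p: float


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("degenerate x variance in regression")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    return slope, intercept, r2


def linreg_compare(x_a, y_a, x_b, y_b) -> RegressionComparison:
    """Per-series OLS fits plus a pooled interaction test of slope equality.

    The slope difference is tested with the t statistic of the
    ``group x time`` interaction coefficient in the pooled model
    ``y ~ 1 + x + group + group:x`` (df = n_total - 4).  Identical series
    give an interaction of exactly 0 and p = 1.
    """
    x_a, y_a = np.asarray(x_a, float), np.asarray(y_a, float)
    x_b, y_b = np.asarray(x_b, float), np.asarray(y_b, float)
    if x_a.size < 3 or x_b.size < 3:
        raise ValueError("each series needs >= 3 points")
    sa, ia_, r2a = _ols_line(x_a, y_a)
    sb, ib_, r2b = _ols_line(x_b, y_b)

    x = np.concatenate([x_a, x_b])
    g = np.concatenate([np.zeros(x_a.size), np.ones(x_b.size)])
    y = np.concatenate([y_a, y_b])
    design = np.column_stack([np.ones_like(x), x, g, g * x])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df = y.size - 4
    diff = float(coef[3])
    if df <= 0 or rank < 4:
        p = float("nan")
    else:
        sigma2 = float(resid @ resid) / df
        cov = sigma2 * np.linalg.pinv(design.T @ design)
        se = math.sqrt(max(cov[3, 3], 0.0))
        if se == 0 or sigma2 == 0:
            # perfect pooled fit: identical slopes give statistic 0 -> p = 1
            p = 1.0 if abs(diff) <= 1e-12 else 0.0
        else:
            t = diff / se
            p = float(2 * sps.t.sf(abs(t), df))
    return RegressionComparison(sa, ia_, r2a, sb, ib_, r2b, diff, p)
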