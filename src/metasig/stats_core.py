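"""Elementary statistics used throughout the pipeline.

Self-contained implementations of Fisher's exact 2x2 test, Welch's t,
the Wilcoxon rank-sum test, Pearson/Spearman correlation and
Benjamini-Hochberg adjustment. Distribution kernels (hypergeometric pmf,
t/normal tails) come from scipy.stats; the test logic is local so its
conventions (two-sided definitions, tie handling, exact-vs-approximate
switch points) are explicit and testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "CorrelationResult",
    "DegenerateStatisticError",
    "fisher_exact_2x2",
    "welch_t",
    "wilcoxon_rank_sum",
    "correlate",
    "bh_adjust",
    "hypergeom_upper_tail",
]


class DegenerateStatisticError(ValueError):
    """Raised when a statistic is undefined for the given input (e.g. zero variance)."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 contingency table of non-negative counts.

    Convention used by the clinical comparisons: row 1 = metastatic,
    row 2 = primary; columns = the two covariate levels.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table total must be >= 1")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    sidedness: str = "two_sided"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    method: str
    n: int


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact_2x2(
    t: ContingencyTable2x2, alternative: str = "two_sided"
) -> TestResult:
    """Fisher's exact test for a 2x2 table.

    Two-sided p sums the hypergeometric probabilities of every table with
    the observed margins whose point probability does not exceed that of
    the observed table (relative tolerance 1e-7) -- the point-probability
    convention used by standard statistical software. The reported
    statistic is the sample odds ratio ad/bc.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    row1, col1, n = a + b, a + c, t.total
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    # hypergeometric: x successes (col 1) in a draw of row1 from n with col1 successes
    support = np.arange(lo, hi + 1)
    pmf = _sps.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    if alternative == "two_sided":
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    elif alternative == "greater":
        p = float(pmf[support >= a].sum())
    elif alternative == "less":
        p = float(pmf[support <= a].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(
        statistic=t.odds_ratio(),
        p_value=min(p, 1.0),
        method="fisher_exact",
        sidedness=alternative,
    )


def hypergeom_upper_tail(k: int, n_draw: int, n_success: int, n_total: int) -> float:
    """P(X >= k) for X ~ Hypergeom(total=n_total, successes=n_success, draws=n_draw)."""
    if k <= 0:
        return 1.0
    return float(_sps.hypergeom.sf(k - 1, n_total, n_success, n_draw))


# ---------------------------------------------------------------------------
# Welch's t


def welch_t(x, y) -> TestResult:
    """Welch's two-sample t with Satterthwaite degrees of freedom, two-sided."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("welch_t needs >= 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    num = x.mean() - y.mean()
    se2 = vx / nx + vy / ny
    if se2 == 0:
        if num == 0:
            return TestResult(0.0, 1.0, "welch_t")
        raise DegenerateStatisticError("zero variance in both groups with unequal means")
    tstat = num / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * float(_sps.t.sf(abs(tstat), df))
    return TestResult(float(tstat), min(p, 1.0), "welch_t")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _rankdata(v: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing the mean of spanned ranks."""
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v), float)
    ranks[order] = np.arange(1, len(v) + 1)
    uniq, inv = np.unique(v, return_inverse=True)
    if len(uniq) < len(v):
        sums = np.bincount(inv, weights=ranks)
        counts = np.bincount(inv)
        ranks = (sums / counts)[inv]
    return ranks


def wilcoxon_rank_sum(x, y, method: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    With ``method="auto"``: exact enumeration of the rank-sum null when
    min(n_x, n_y) <= 8 and the pooled sample is tie-free; otherwise a normal
    approximation with tie and continuity corrections. ``"exact"`` and
    ``"normal"`` force a path. The statistic is the rank sum of ``x``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("wilcoxon_rank_sum needs nonempty samples")
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate([x, y])
    ranks = _rankdata(pooled)
    w = float(ranks[:nx].sum())
    n = nx + ny
    has_ties = len(np.unique(pooled)) < n
    use_exact = method == "exact" or (
        method == "auto" and min(nx, ny) <= 8 and not has_ties
    )
    if use_exact:
        if has_ties:
            raise ValueError("exact path is undefined for tied samples")
        # enumerate all C(n, nx) assignments of ranks to x
        all_ranks = np.arange(1, n + 1)
        m = min(nx, ny)
        target = w if nx <= ny else (n * (n + 1) / 2 - w)
        sums = np.array([sum(cmb) for cmb in combinations(all_ranks, m)], float)
        mean_w = m * (n + 1) / 2
        dev = abs(target - mean_w)
        p = float(np.mean(np.abs(sums - mean_w) >= dev - 1e-12))
        return TestResult(w, min(p, 1.0), "wilcoxon_exact")
    mean_w = nx * (n + 1) / 2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var_w = nx * ny / 12 * (n + 1 - tie_term)
    if var_w == 0:
        return TestResult(w, 1.0, "wilcoxon_normal")
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    z = max(z, 0.0)
    p = 2 * float(_sps.norm.sf(z))
    return TestResult(w, min(p, 1.0), "wilcoxon_normal")


# ---------------------------------------------------------------------------
# Correlation


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson r or Spearman rho (average ranks) with a t-transform p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("correlation p-value needs n >= 3")
    if method == "spearman":
        x, y = _rankdata(x), _rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = math.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        raise DegenerateStatisticError("zero variance: correlation undefined")
    r = float((xd * yd).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        tstat = r * math.sqrt((n - 2) / (1 - r**2))
        p = 2 * float(_sps.t.sf(abs(tstat), n - 2))
    return CorrelationResult(r, min(p, 1.0), method, n)


# ---------------------------------------------------------------------------
# Multiple testing


def bh_adjust(p) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0,1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n, float)
    out[order] = adj
    return out.tolist()
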