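"""Shared nonparametric statistics.

Normal approximations are used throughout (average ranks for ties); the
test suite validates the small-sample behaviour against exhaustive
permutation oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class CorrelationResult:
    rho: float
    n: int
    ci_low: float
    ci_high: float
    p: float


def spearman_ci(x, y, level: float = 0.95) -> CorrelationResult:
    """Spearman rank correlation with a Fisher-transform confidence interval.

    rho uses average ranks; the CI back-transforms ``z +/- z_crit/sqrt(n-3)``;
    the p-value is a two-sided normal approximation on the Fisher z scale.
    Raises on a constant vector (rho undefined).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and equal length")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: rho undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        z = math.inf if rho > 0 else -math.inf
    else:
        z = math.atanh(rho)
    se = 1.0 / math.sqrt(n - 3)
    zc = sps.norm.ppf(0.5 + level / 2)
    ci_low = math.tanh(z - zc * se) if math.isfinite(z) else rho
    ci_high = math.tanh(z + zc * se) if math.isfinite(z) else rho
    p = 2 * sps.norm.sf(abs(z) / se) if math.isfinite(z) else 0.0
    return CorrelationResult(rho, n, ci_low, ci_high, float(p))


@dataclass
class ContingencyTable:
    """2x2 counts; rows = group (e.g. candidate vs random), cols = outcome."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(v < 0 for v in cells):
            raise ValueError("counts must be non-negative")
        if sum(cells) <= 0:
            raise ValueError("table is empty")


@dataclass
class LogOddsResult:
    log_odds: float
    se: float
    p: float
    table: ContingencyTable


def log_odds(table: ContingencyTable, haldane: bool = True) -> LogOddsResult:
    """Natural-log odds ratio of a 2x2 table with Wald p-value.

    With ``haldane``, 0.5 is added to every cell iff any cell is zero.
    ``se = sqrt(sum 1/cell)``; p from the two-sided Wald z test.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if 0 in (a, b, c, d):
        raise ZeroDivisionError("zero cell without Haldane correction")
    lo = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = 2 * sps.norm.sf(abs(lo) / se)
    return LogOddsResult(lo, se, float(p), table)


@dataclass
class TrendResult:
    statistic: float
    z: float
    p: float
    alternative: str


def jonckheere(
    groups: Sequence[Sequence[float]], alternative: str = "decreasing"
) -> TrendResult:
    """Jonckheere-Terpstra test for an ordered location trend across groups.

    ``JT = sum over ordered group pairs (i<j) of the Mann-Whitney count
    #(x_i < x_j) + 0.5 #(x_i == x_j)``.  The normal approximation uses the
    tie-adjusted variance; ``alternative`` is "increasing", "decreasing"
    (default, the direction of the coverage-vs-stalling claim) or
    "two-sided".  With every observation tied, z = 0 and p = 0.5 (1.0 for
    two-sided).
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if alternative not in ("increasing", "decreasing", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")

    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            xi = groups[i][:, None]
            xj = groups[j][None, :]
            jt += float((xi < xj).sum() + 0.5 * (xi == xj).sum())

    ns = np.array([g.size for g in groups], dtype=np.float64)
    N = ns.sum()
    pooled = np.concatenate(groups)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(np.float64)

    mean = (N * N - (ns**2).sum()) / 4.0
    term1 = (
        N * (N - 1) * (2 * N + 5)
        - (ns * (ns - 1) * (2 * ns + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    ) / 72.0
    term2 = 0.0
    term3 = 0.0
    if N > 2:
        term2 = ((ns * (ns - 1) * (ns - 2)).sum() * (t * (t - 1) * (t - 2)).sum()) / (
            36.0 * N * (N - 1) * (N - 2)
        )
    if N > 1:
        term3 = ((ns * (ns - 1)).sum() * (t * (t - 1)).sum()) / (8.0 * N * (N - 1))
    var = term1 + term2 + term3
    if var <= 0:
        z = 0.0
    else:
        # continuity correction: JT is integer/half-integer valued
        delta = jt - mean
        delta -= math.copysign(min(0.5, abs(delta)), delta)
        z = delta / math.sqrt(var)
    if alternative == "increasing":
        p = sps.norm.sf(z)
    elif alternative == "decreasing":
        p = sps.norm.cdf(z)
    else:
        p = 2 * sps.norm.sf(abs(z)) if z != 0 else 1.0
    return TrendResult(jt, float(z), float(p), alternative)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (k-1 df).

    All observations identical returns (0.0, 1.0) rather than erroring.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 2:
        raise ValueError("need >= 2 total observations")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def trimmed_mean(values: Sequence[float], trim: float = 0.05) -> float:
    """Mean after removing ``ceil(trim * n)`` values from each tail.

    The ceiling rule guarantees at least one value is dropped per tail for
    any positive trim, which is the reading of "5% trimmed mean" adopted
    for small classes.
    """
    v = np.sort(np.asarray(values, dtype=np.float64))
    if v.size == 0:
        raise ValueError("empty input")
    if not (0 <= trim < 0.5):
        raise ValueError("trim must be in [0, 0.5)")
    k = math.ceil(trim * v.size) if trim > 0 else 0
    if 2 * k >= v.size:
        raise ValueError("trim removes all values")
    return float(v[k:v.size - k].mean())
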