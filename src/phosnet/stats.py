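"""Small-sample nonparametric tests used throughout the pipeline.

Every group comparison in the package reduces to one of three procedures:
the Mann-Whitney rank-sum test for numeric metrics, Fisher's exact test for
flag (2x2) metrics, and the Spearman rank correlation. Sample sizes in
enzyme-class comparisons are often small (tens of genes per class), so each
test carries an exact small-sample path alongside the usual large-sample
approximation.

Conventions
-----------
* ``tail`` is one of ``"greater"``, ``"less"``, ``"two-sided"`` and always
  refers to the *first* sample (or the top-left cell of a 2x2 table)
  relative to the second.
* The rank-sum statistic reported is U of the first sample (number of
  (x, y) pairs with x > y, ties counted 1/2).
* Exact two-sided p-values are twice the smaller one-sided p-value,
  clipped to 1.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "rank_sum_test",
    "fisher_2x2",
    "spearman_corr",
    "significance_stars",
    "EXACT_TOTAL_N",
]

#: largest combined sample size for which the rank-sum test enumerates the
#: exact permutation null by default
EXACT_TOTAL_N = 20

TAILS = ("greater", "less", "two-sided")


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-group comparison.

    Attributes
    ----------
    metric : str
        Name of the metric compared (e.g. ``"abundance"``).
    group_labels : tuple of str
        Names of the two groups, first group first.
    group_sizes : tuple of int
        Number of non-missing observations per group.
    group_summaries : tuple of float
        Median (numeric metrics) or fraction of flagged records (flag
        metrics) per group.
    test : str
        ``"mann-whitney-exact"``, ``"mann-whitney-asymptotic"``,
        ``"fisher-exact"`` or ``"spearman"``.
    tail : str
        ``"greater"``, ``"less"`` or ``"two-sided"`` (first group relative
        to second).
    statistic : float
        U of the first group (rank-sum), odds ratio (Fisher) or rho
        (Spearman).
    p_value : float
    stars : str
        Significance marker per the banding of :func:`significance_stars`.
    """

    metric: str
    group_labels: tuple[str, str]
    group_sizes: tuple[int, int]
    group_summaries: tuple[float, float]
    test: str
    tail: str
    statistic: float
    p_value: float
    stars: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_a"], d["group_b"] = d.pop("group_labels")
        d["n_a"], d["n_b"] = d.pop("group_sizes")
        d["summary_a"], d["summary_b"] = d.pop("group_summaries")
        return d


def _clean(sample: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError(f"sample {name!r} is empty after missing-value removal")
    return arr


def _u_statistic(x: np.ndarray, y: np.ndarray, axis: int = -1) -> np.ndarray:
    """U of the first sample from pooled ranks (ties get average rank)."""
    nx = x.shape[axis]
    pooled = np.concatenate([x, y], axis=axis)
    ranks = sps.rankdata(pooled, axis=axis)
    rank_sum_x = np.take(ranks, np.arange(nx), axis=axis).sum(axis=axis)
    return rank_sum_x - nx * (nx + 1) / 2.0


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    tail: str = "two-sided",
    method: str = "auto",
    metric: str = "",
    labels: tuple[str, str] = ("A", "B"),
) -> ComparisonResult:
    """Mann-Whitney rank-sum test of two independent samples.

    Parameters
    ----------
    x, y
        Numeric samples; NaNs are dropped before testing.
    tail
        Alternative hypothesis for ``x`` relative to ``y``.
    method
        ``"exact"`` enumerates the full permutation null (ties handled by
        average ranks, so the enumeration remains valid with ties);
        ``"asymptotic"`` uses the normal approximation with tie and
        continuity corrections; ``"auto"`` picks exact when
        ``len(x) + len(y) <= EXACT_TOTAL_N``.

    Returns
    -------
    ComparisonResult
        ``statistic`` is U of the first sample.
    """
    if tail not in TAILS:
        raise ValueError(f"unknown tail {tail!r}")
    xa = _clean(x, "x")
    ya = _clean(y, "y")
    n_total = xa.size + ya.size
    if method == "auto":
        method = "exact" if n_total <= EXACT_TOTAL_N else "asymptotic"

    u1 = float(_u_statistic(xa, ya))
    if method == "exact":
        res = sps.permutation_test(
            (xa, ya),
            _u_statistic,
            permutation_type="independent",
            alternative=tail,
            n_resamples=np.inf,
        )
        p = float(res.pvalue)
        test_name = "mann-whitney-exact"
    elif method == "asymptotic":
        res = sps.mannwhitneyu(
            xa, ya, alternative=tail, method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
        test_name = "mann-whitney-asymptotic"
    else:
        raise ValueError(f"unknown method {method!r}")

    return ComparisonResult(
        metric=metric,
        group_labels=labels,
        group_sizes=(int(xa.size), int(ya.size)),
        group_summaries=(float(np.median(xa)), float(np.median(ya))),
        test=test_name,
        tail=tail,
        statistic=u1,
        p_value=min(p, 1.0),
        stars=significance_stars(p),
    )


def fisher_2x2(
    a: int,
    b: int,
    c: int,
    d: int,
    tail: str = "two-sided",
    metric: str = "",
    labels: tuple[str, str] = ("A", "B"),
) -> ComparisonResult:
    """Fisher's exact test on the 2x2 table ``[[a, b], [c, d]]``.

    Rows are groups, columns are flag states (flagged, not flagged). The
    two-sided p-value sums hypergeometric probabilities no larger than
    that of the observed table. ``tail="greater"`` tests enrichment of the
    flag in the first row.
    """
    counts = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in counts):
        raise ValueError(f"counts must be nonnegative integers, got {counts}")
    a, b, c, d = (int(v) for v in counts)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError(f"table {counts} has a zero margin")
    if tail not in TAILS:
        raise ValueError(f"unknown tail {tail!r}")

    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative=tail)
    return ComparisonResult(
        metric=metric,
        group_labels=labels,
        group_sizes=(a + b, c + d),
        group_summaries=(a / (a + b), c / (c + d)),
        test="fisher-exact",
        tail=tail,
        statistic=float(odds),
        p_value=float(p),
        stars=significance_stars(float(p)),
    )


def _rho_statistic(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_corr(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Spearman rank correlation with an exact permutation p at small n.

    Pairs with a missing value in either coordinate are dropped. For
    ``n >= 10`` (or ``method="approx"``) the p-value comes from the usual
    t approximation; for smaller samples every pairing permutation is
    enumerated. Constant input has undefined rank correlation and raises.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    n = xa.size
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("rank correlation undefined for constant input")

    rho = _rho_statistic(xa, ya)
    if method == "auto":
        method = "approx" if n >= 10 else "exact"
    if method == "approx":
        p = float(sps.spearmanr(xa, ya).pvalue)
    elif method == "exact":
        res = sps.permutation_test(
            (xa, ya),
            lambda xs, ys: _rho_statistic(xs, ys),
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=np.inf,
            vectorized=False,
        )
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return rho, min(p, 1.0)


def significance_stars(p: float, symbol: str = "*") -> str:
    """Band a p-value into the conventional significance markers.

    Three symbols for p < 1e-6, two for p < 1e-3, one for p < 0.05, empty
    otherwise. ``symbol="+"`` yields the marker style used for
    group-versus-genome comparisons.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p < 1e-6:
        return symbol * 3
    if p < 1e-3:
        return symbol * 2
    if p < 0.05:
        return symbol
    return ""
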