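"""Two-group comparison statistics for outcome-stratified cohorts.

Implements the three tools used to compare a died-of-cancer (DOC) group
against survivors on histogram and clinical parameters:

* Cohen's d with the pooled standard deviation
  ``sd_pooled = sqrt([SD1^2 (N1-1) + SD2^2 (N2-1)] / (N1 + N2 - 2))``,
  stored signed (group 1 minus group 2) with the magnitude exposed for
  reporting;
* Welch's unequal-variance t test with Welch-Satterthwaite degrees of
  freedom (kept fractional);
* the Freeman-Halton exact test for 2 x k contingency tables, a
  generalisation of Fisher's 2 x 2 exact test. The two-sided p-value
  follows the probability-mass rule: the sum of hypergeometric
  probabilities of every table with the observed margins whose
  probability does not exceed that of the observed table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .exceptions import CapacityError, DegenerateVarianceError

__all__ = [
    "GroupSummary",
    "EffectSize",
    "WelchResult",
    "cohens_d",
    "welch_test",
    "fisher_exact_2xk",
]

#: absolute slack when comparing table probabilities to the observed one
_PROB_SLACK = 1e-12


@dataclass(frozen=True)
class GroupSummary:
    """Mean, standard deviation and size of one group of one parameter."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.sd < 0:
            raise ValueError("standard deviation must be >= 0")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        x = np.asarray(values, dtype=float)
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        return cls(mean=float(x.mean()), sd=sd, n=int(x.size))


@dataclass(frozen=True)
class EffectSize:
    """Signed Cohen's d and the pooled sd it was standardised by."""

    d: float
    sd_pooled: float

    @property
    def magnitude(self) -> float:
        return abs(self.d)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def cohens_d(g1: GroupSummary, g2: GroupSummary) -> EffectSize:
    """Standardised mean difference (group 1 minus group 2), pooled sd.

    Raises
    ------
    ValueError
        If either group has fewer than two observations, or if the
        pooled sd vanishes while the means differ (infinite effect).
    """
    if g1.n < 2 or g2.n < 2:
        raise ValueError("Cohen's d needs at least 2 observations per group")
    sd_pooled = float(
        np.sqrt(
            (g1.sd**2 * (g1.n - 1) + g2.sd**2 * (g2.n - 1)) / (g1.n + g2.n - 2)
        )
    )
    diff = g1.mean - g2.mean
    if sd_pooled == 0.0:
        if diff == 0.0:
            return EffectSize(d=0.0, sd_pooled=0.0)
        raise ValueError("pooled sd is zero with unequal means: effect size infinite")
    return EffectSize(d=diff / sd_pooled, sd_pooled=sd_pooled)


def welch_test(g1: GroupSummary, g2: GroupSummary) -> WelchResult:
    """Welch's two-sided unequal-variance t test from group summaries."""
    if g1.n < 2 or g2.n < 2:
        raise ValueError("Welch's test needs at least 2 observations per group")
    if g1.sd == 0.0 and g2.sd == 0.0:
        raise DegenerateVarianceError("both group variances are zero")
    res = sps.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=False
    )
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return WelchResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("expected a 2 x k table with k >= 2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    t = t.astype(int)
    if np.any(t.sum(axis=1) == 0):
        raise ValueError("both row sums must be positive")
    return t


def _row_candidates(cols: np.ndarray, r1: int) -> Iterator[tuple[int, ...]]:
    """All first rows (a_1..a_k) with 0 <= a_j <= col_j and sum r1."""
    k = len(cols)
    tail = np.concatenate([np.cumsum(cols[::-1])[::-1][1:], [0]])

    def rec(j: int, rem: int):
        if j == k - 1:
            if 0 <= rem <= cols[j]:
                yield (rem,)
            return
        lo = max(0, rem - int(tail[j]))
        hi = min(int(cols[j]), rem)
        for a in range(lo, hi + 1):
            for rest in rec(j + 1, rem - a):
                yield (a,) + rest

    yield from rec(0, r1)


def _table_probabilities(table) -> tuple[float, np.ndarray]:
    """Observed-table probability and probabilities of all margin-preserving tables."""
    t = _validate_table(table)
    cols = t.sum(axis=0)
    r1 = int(t[0].sum())
    n = int(t.sum())
    denom = float(_log_comb(np.array(n), np.array(r1)))
    p_obs = float(np.exp(_log_comb(cols, t[0]).sum() - denom))
    probs = np.array(
        [
            np.exp(_log_comb(cols, np.array(a)).sum() - denom)
            for a in _row_candidates(cols, r1)
        ]
    )
    return p_obs, probs


def fisher_exact_2xk(table, max_tables: int = 1_000_000) -> float:
    """Two-sided Freeman-Halton exact test for a 2 x k contingency table.

    Enumerates every table with the observed margins; the p-value is the
    total probability of tables no more probable than the observed one
    (within a 1e-12 absolute slack). For k = 2 this coincides with the
    classical two-sided Fisher exact test.

    Raises
    ------
    CapacityError
        If the enumeration bound ``prod(col_j + 1)`` exceeds
        ``max_tables``; a Monte-Carlo approximation should be used
        instead at that scale.
    """
    t = _validate_table(table)
    cols = t.sum(axis=0)
    bound = int(np.prod(cols.astype(np.int64) + 1))
    if bound > max_tables:
        raise CapacityError(
            f"~{bound} candidate tables exceed the exact budget of {max_tables}; "
            "use a Monte-Carlo approximation"
        )
    p_obs, probs = _table_probabilities(t)
    return float(probs[probs <= p_obs + _PROB_SLACK].sum())
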