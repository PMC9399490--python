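"""Cohort-level hypothesis tests: Fisher's exact, Mann-Whitney U, chi-squared.

Fisher's two-sided p follows the point-probability convention (the sum of
hypergeometric probabilities of every table with the observed margins whose
probability does not exceed that of the observed table), accumulated in
exact rational arithmetic so tied probabilities are never lost to rounding.
This is the convention of R's ``fisher.test`` and scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

#: Largest n_A * n_B for which the Mann-Whitney p-value uses the exact
#: permutation distribution (ties force the asymptotic path regardless).
MWU_EXACT_LIMIT = 400


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"counts must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("contingency table is all zero")

    @classmethod
    def from_array(cls, table: Sequence[Sequence[int]]) -> "ContingencyTable2x2":
        (a, b), (c, d) = table
        return cls(int(a), int(b), int(c), int(d))

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class TestResult:
    test: str
    p_value: float
    statistic: Optional[float] = None
    sidedness: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _hypergeom_pmf(k: int, r1: int, r2: int, c1: int) -> Fraction:
    """P(first-row 'yes' count = k) for fixed margins, as an exact rational."""
    return Fraction(comb(r1, k) * comb(r2, c1 - k), comb(r1 + r2, c1))


def fisher_exact_two_sided(t: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    All tables sharing the observed margins are enumerated; those at most as
    probable as the observed table contribute to p.  Exact rationals make the
    'at most as probable' comparison free of floating-point ties.
    """
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    k_min = max(0, c1 - r2)
    k_max = min(c1, r1)
    p_obs = _hypergeom_pmf(t.a, r1, r2, c1)
    p = Fraction(0)
    for k in range(k_min, k_max + 1):
        pk = _hypergeom_pmf(k, r1, r2, c1)
        if pk <= p_obs:
            p += pk
    return TestResult(test="fisher_exact", p_value=float(min(p, Fraction(1))))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney U test comparing two independent samples.

    U_A counts pairs (a, b) with a > b, ties counting one half; the reported
    statistic is min(U_A, U_B).  The p-value is exact (permutation
    distribution) for small tie-free samples, otherwise a tie-corrected
    normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = x.size, y.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
    u_b = n_a * n_b - u_a
    has_ties = np.unique(np.concatenate([x, y])).size < n_a + n_b
    if n_a * n_b <= MWU_EXACT_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    p = float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )
    return TestResult(test="mann_whitney_u", statistic=min(u_a, u_b), p_value=p)


def u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """U_A of group x over group y (rank formula; ties contribute one half)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_a = x.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)


def chi_squared_independence(
    t: ContingencyTable2x2, correction: bool = False
) -> TestResult:
    """Pearson chi-squared test of independence on a 2x2 table (1 d.f.).

    No continuity correction by default; Yates correction via ``correction``.
    """
    table = t.as_array()
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-squared requires all row/column margins > 0")
    res = sps.chi2_contingency(table, correction=correction)
    return TestResult(
        test="chi_squared", statistic=float(res.statistic), p_value=float(res.pvalue)
    )
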