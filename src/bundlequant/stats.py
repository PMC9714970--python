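"""Group statistics: exact 2×2 test and percent-of-control normalisation.

The two-sided Fisher exact p-value follows the standard exact
convention: with all margins fixed, sum the hypergeometric probabilities
of every table that is no more probable than the observed one.  The
hypergeometric weights C(r1, k)·C(r2, c1−k) share the denominator
C(n, c1), so the "no more probable" comparison is carried out on exact
integers — no floating-point epsilon is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, sqrt
from typing import Sequence

import numpy as np

from .morphometry import ContingencyTable2x2

__all__ = [
    "TestResult",
    "fisher_exact_2x2",
    "PercentOfControl",
    "percent_of_control",
]


@dataclass
class TestResult:
    """Uniform wrapper for a hypothesis-test outcome."""

    method: str
    p_value: float
    statistic: float | None = None
    table: ContingencyTable2x2 | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def fisher_exact_2x2(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test on a 2×2 table.

    All margins must be positive.  The odds ratio (sample, ad/bc) is
    reported as the statistic, infinite or undefined cells permitting.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = table.n
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        raise ValueError("all margins of the 2x2 table must be positive")

    k_lo = max(0, c1 - r2)
    k_hi = min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(k_lo, k_hi + 1)}
    w_obs = weights[a]
    numer = sum(w for w in weights.values() if w <= w_obs)
    p = float(Fraction(numer, comb(n, c1)))

    odds = float("nan")
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = float("inf")
    return TestResult(
        method="fisher_exact_two_sided",
        p_value=min(p, 1.0),
        statistic=odds,
        table=table,
        n=n,
    )


@dataclass
class PercentOfControl:
    """Values normalised to the control-group mean (percent)."""

    percents: np.ndarray
    mean: float
    sem: float
    n: int


def percent_of_control(
    values: Sequence[float], control_values: Sequence[float]
) -> PercentOfControl:
    """Express each value as 100 × value / mean(control).

    The summary is mean ± sem (sd with n−1 denominator over √n).  A
    non-positive control mean is an error.
    """
    values = np.asarray(values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    cmean = float(control.mean())
    if cmean <= 0:
        raise ValueError(f"control mean must be > 0, got {cmean}")
    percents = 100.0 * values / cmean
    n = int(percents.size)
    mean = float(percents.mean()) if n else float("nan")
    sem = float(percents.std(ddof=1) / sqrt(n)) if n > 1 else float("nan")
    return PercentOfControl(percents, mean, sem, n)
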