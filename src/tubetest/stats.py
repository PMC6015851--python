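"""Inferential procedures for contest analyses.

Three classical tests, wrapped with the exact conventions the dominance
analyses rely on:

* a one-degree-of-freedom chi-square goodness of fit comparing observed
  win counts in a two-way contrast against an even split, without
  continuity correction (for wins a vs b the statistic reduces to
  (a-b)^2 / (a+b));
* a pooled-variance two-sample Student t-test (df = n_a + n_b - 2);
* the Pearson product-moment correlation with a two-sided p-value from
  the t-transform on n-2 degrees of freedom, plus the least-squares
  slope of y on x (a slope below 1 — a regression line shallower than
  45 degrees — indicates regression of the second measurement toward
  the mean, i.e. imperfectly preserved individual differences).

The heavy lifting is scipy.stats; this module fixes the conventions and
returns typed results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "WinContrast",
    "MeanContrast",
    "CorrelationResult",
    "chi2_even_split",
    "two_sample_t",
    "pearson",
]


@dataclass(frozen=True)
class WinContrast:
    """Chi-square contrast of two win counts against an even split."""

    label_a: str
    label_b: str
    wins_a: int
    wins_b: int
    chi2: float
    df: int
    p: float

    @property
    def total(self) -> int:
        return self.wins_a + self.wins_b


@dataclass(frozen=True)
class MeanContrast:
    """Two-sample mean comparison (Student t, pooled by default)."""

    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with regression slope of y on x."""

    n: int
    r: float
    p: float
    slope: float


def chi2_even_split(
    wins_a: int, wins_b: int, label_a: str = "A", label_b: str = "B"
) -> WinContrast:
    """Goodness-of-fit chi-square of (wins_a, wins_b) vs a 50/50 split.

    Expected count is total/2 in each category; the statistic is the
    uncorrected sum of (O-E)^2/E on 1 degree of freedom.  No Yates
    continuity correction is applied.
    """
    if wins_a < 0 or wins_b < 0:
        raise ValueError("win counts must be non-negative")
    total = wins_a + wins_b
    if total == 0:
        raise ValueError("cannot contrast zero contests")
    chi2, p = sps.chisquare([wins_a, wins_b])
    return WinContrast(
        label_a=label_a,
        label_b=label_b,
        wins_a=wins_a,
        wins_b=wins_b,
        chi2=float(chi2),
        df=1,
        p=float(p),
    )


def two_sample_t(
    values_a: Sequence[float], values_b: Sequence[float], pooled: bool = True
) -> MeanContrast:
    """Two-sample t-test; pooled (Student) variance by default.

    With pooling, df = n_a + n_b - 2 exactly.  A degenerate case is
    handled explicitly: zero pooled variance with equal means gives
    t = 0 (no evidence either way); zero variance with unequal means is
    an error rather than an infinite statistic.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if pooled:
        df = a.size + b.size - 2
    else:
        # Welch-Satterthwaite df (not the default convention here)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        denom = va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        df = int(round((va + vb) ** 2 / denom)) if denom > 0 else a.size + b.size - 2
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return MeanContrast(a.size, b.size, float(a.mean()), float(b.mean()),
                                0.0, df, 1.0)
        raise ValueError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=pooled)
    return MeanContrast(
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=float(t),
        df=df,
        p=float(p),
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with two-sided p (t-transform, n-2 df) and LS slope of y on x."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least three observations")
    if np.ptp(xa) == 0.0 or np.ptp(ya) == 0.0:
        raise ValueError("correlation undefined for a constant input")
    res = sps.pearsonr(xa, ya)
    slope = float(np.polyfit(xa, ya, 1)[0])
    return CorrelationResult(
        n=int(xa.size), r=float(res.statistic), p=float(res.pvalue), slope=slope
    )
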