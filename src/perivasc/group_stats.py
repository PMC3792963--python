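"""Summary statistics and group comparisons.

Results are reported as mean ± sample SD (n−1 denominator).  The two
sacrifice-time subgroups of each treatment arm have equal n by design, so
a "Total" row is the exact pooled-sample summary reconstructed from the
two subgroup summaries.  Arms are compared with one-way ANOVA followed by
Fisher's LSD-t pairwise test (unadjusted, by definition of LSD), both
available from raw values or from (n, mean, sd) summaries alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateAnova, InsufficientData, UnequalSubgroups


@dataclass(frozen=True)
class SummaryStats:
    """n, sample mean and sample SD (n−1 denominator) of one cell."""

    n: int
    mean: float
    sd: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientData(f"summary requires n >= 2, got n={self.n}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    mse_within: float


def summarize(values: Sequence[float], units: str = "") -> SummaryStats:
    """Sample mean and n−1 standard deviation of a list of values."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientData(f"need at least 2 values, got {arr.size}")
    return SummaryStats(
        n=int(arr.size), mean=float(arr.mean()), sd=float(arr.std(ddof=1)), units=units
    )


def combine_subgroups(a: SummaryStats, b: SummaryStats) -> SummaryStats:
    """Pool two equal-n subgroup summaries into one sample summary.

    With n = a.n = b.n, the pooled mean is the average of the subgroup
    means and the pooled sample SD is

        sqrt( [ (n−1)(sa² + sb²) + n((ma−m)² + (mb−m)²) ] / (2n−1) ),

    i.e. exactly the n−1 SD of the 2n underlying values reconstructed from
    their sufficient statistics.
    """
    if a.n != b.n:
        raise UnequalSubgroups(f"subgroup sizes differ: {a.n} vs {b.n}")
    n = a.n
    mean = (a.mean + b.mean) / 2.0
    ss = (n - 1) * (a.sd**2 + b.sd**2) + n * ((a.mean - mean) ** 2 + (b.mean - mean) ** 2)
    return SummaryStats(n=2 * n, mean=mean, sd=math.sqrt(ss / (2 * n - 1)), units=a.units)


def _is_summary_input(groups: Sequence) -> bool:
    return all(isinstance(g, SummaryStats) for g in groups)


def anova_oneway(groups: Sequence[Sequence[float]] | Sequence[SummaryStats]) -> AnovaResult:
    """One-way fixed-effects ANOVA from raw values or summary statistics.

    The summary form uses SSB = Σ nᵢ(mᵢ − m̄)² (m̄ the grand mean) and
    SSW = Σ (nᵢ−1)sᵢ²; the raw form accumulates sums of squares directly.
    Both give identical F up to floating-point error.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    if _is_summary_input(groups):
        ns = np.array([g.n for g in groups], dtype=float)
        means = np.array([g.mean for g in groups], dtype=float)
        ssw = float(sum((g.n - 1) * g.sd**2 for g in groups))
        grand = float((ns * means).sum() / ns.sum())
        ssb = float((ns * (means - grand) ** 2).sum())
        n_total = int(ns.sum())
    else:
        arrs = [np.asarray(g, dtype=float) for g in groups]
        if any(a.size < 2 for a in arrs):
            raise InsufficientData("each group needs n >= 2")
        n_total = sum(a.size for a in arrs)
        grand = float(np.concatenate(arrs).mean())
        ssb = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrs))
        ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if ssw == 0.0:
        raise DegenerateAnova("zero within-group variance in every group")
    msb = ssb / df_between
    mse = ssw / df_within
    F = msb / mse
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(
        F=F, df_between=df_between, df_within=df_within, p_value=p, mse_within=mse
    )


def lsd_t(a: SummaryStats, b: SummaryStats, anova: AnovaResult) -> tuple[float, float]:
    """Fisher's LSD-t comparison of two groups after a one-way ANOVA.

    t = (ma − mb) / sqrt(MSE · (1/na + 1/nb)), two-sided p on the ANOVA
    within-group degrees of freedom.  No multiplicity adjustment is
    applied; that is the definition of the LSD procedure.
    """
    if anova.mse_within <= 0:
        raise DegenerateAnova("mse_within must be positive for LSD-t")
    se = math.sqrt(anova.mse_within * (1.0 / a.n + 1.0 / b.n))
    t = (a.mean - b.mean) / se
    p = float(2.0 * stats.t.sf(abs(t), anova.df_within))
    return t, p


def round_half_away(x: float, decimals: int = 2) -> float:
    """Report rounding: half away from zero (the convention of the tables).

    Operates on the shortest decimal representation of ``x`` so that
    values that are exact decimal halves (59.685) round up as a human
    would round them, despite binary floating point storing them a hair
    below the half.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-decimals)
    magnitude = float(Decimal(repr(abs(float(x)))).quantize(q, rounding=ROUND_HALF_UP))
    return math.copysign(magnitude, x)
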