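"""Non-parametric tolerance limits, percentile tables, equivalent-score bands.

The clinical cut-offs are one-sided non-parametric tolerance limits: order
statistics that bracket the population 5th centile (on the impaired tail)
with 95% confidence.  With coverage P and confidence g, the number of sample
values falling below the population (1-P) quantile is Binomial(n, 1-P), so

* the OUTER limit is the r-th order statistic from the impaired tail, with r
  the largest rank such that Pr[Bin(n, 1-P) >= r] >= g - at least r
  observations beyond the true quantile with confidence g, so the r-th is on
  its impaired side;
* the INNER limit uses the smallest rank s with Pr[Bin(n, 1-P) < s] >= g.

Scores beyond the outer limit are classed impaired; between the limits,
uncertain.  Equivalent scores (ES) are rank-based: ES0 ends at the outer
limit, ES4 starts at the median, and ES1/2/3 split the region in between at
the 20% and 35% cumulative ranks counted from the impaired tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .types import Direction, round_half_away

#: Percentile levels as printed in the published tables.
DEFAULT_PERCENTILE_LEVELS: Tuple[float, ...] = (
    1, 2, 3, 4, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50,
    55, 60, 65, 70, 75, 80, 85, 90, 95, 99,
)


class ToleranceSide(str, Enum):
    LOWER_TAIL_IS_IMPAIRED = "lower_tail_is_impaired"
    UPPER_TAIL_IS_IMPAIRED = "upper_tail_is_impaired"


@dataclass(frozen=True)
class ToleranceSpec:
    """Coverage P, confidence gamma, and which tail is the impaired one."""

    coverage: float = 0.95
    confidence: float = 0.95
    side: ToleranceSide = ToleranceSide.LOWER_TAIL_IS_IMPAIRED

    def __post_init__(self) -> None:
        if not 0 < self.coverage < 1:
            raise ValueError("coverage must be in (0, 1)")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        object.__setattr__(self, "side", ToleranceSide(self.side))


@dataclass(frozen=True)
class ESBandSpec:
    """Cumulative rank proportions of the ES1/2, ES2/3 and ES3/4 boundaries."""

    cuts: Tuple[float, float, float] = (0.20, 0.35, 0.50)

    def __post_init__(self) -> None:
        c = tuple(self.cuts)
        object.__setattr__(self, "cuts", c)
        if len(c) != 3 or not all(a < b for a, b in zip(c, c[1:])):
            raise ValueError("ES cut proportions must be 3 strictly increasing values")
        if c[-1] != 0.50:
            raise ValueError("the ES3/4 boundary must sit at the median (0.50)")


class NoValidToleranceLimit(ValueError):
    """Raised when n is too small for a distribution-free tolerance limit."""


def tolerance_ranks(n: int, spec: ToleranceSpec = ToleranceSpec()) -> Tuple[int, int]:
    """(outer_rank, inner_rank) counted from the impaired tail, 1-based.

    Raises :class:`NoValidToleranceLimit` when even the most extreme order
    statistic cannot guarantee the coverage (for P = g = 0.95 this needs
    n >= 59, since 0.95**59 is the first power below 0.05).
    """
    if n < 1:
        raise NoValidToleranceLimit("empty sample")
    p = 1.0 - spec.coverage
    gamma = spec.confidence
    # Pr[Bin(n, p) >= 1] = 1 - (1-p)^n must reach gamma for any limit to exist
    if stats.binom.sf(0, n, p) < gamma:
        raise NoValidToleranceLimit(
            f"n={n} too small for a one-sided {spec.coverage:.0%} tolerance limit "
            f"at {spec.confidence:.0%} confidence"
        )
    outer = 1
    while stats.binom.sf(outer, n, p) >= gamma:  # Pr[Bin >= outer+1]
        outer += 1
    inner = outer
    while stats.binom.cdf(inner - 1, n, p) < gamma:  # Pr[Bin < inner]
        inner += 1
    return outer, inner


def minimum_n(spec: ToleranceSpec = ToleranceSpec()) -> int:
    """Smallest sample size admitting a distribution-free tolerance limit."""
    n = 1
    p = 1.0 - spec.coverage
    while stats.binom.sf(0, n, p) < spec.confidence:
        n += 1
    return n


def tolerance_limits(
    scores: Sequence[float], spec: ToleranceSpec = ToleranceSpec()
) -> Tuple[float, float]:
    """(outer, inner) tolerance limits: order statistics from the impaired tail."""
    values = np.sort(np.asarray(scores, dtype=float))
    outer_rank, inner_rank = tolerance_ranks(len(values), spec)
    if spec.side is ToleranceSide.LOWER_TAIL_IS_IMPAIRED:
        return float(values[outer_rank - 1]), float(values[inner_rank - 1])
    return float(values[-outer_rank]), float(values[-inner_rank])


def percentile_table(
    scores: Sequence[float],
    levels: Sequence[float] = DEFAULT_PERCENTILE_LEVELS,
    direction: Direction = Direction.HIGHER_BETTER,
    ndigits: int = 1,
) -> dict[float, float]:
    """Empirical quantiles at the given levels, oriented so that a higher
    percentile always means better performance (for time scales, level L maps
    to the (100-L)-th quantile of the raw distribution)."""
    values = np.asarray(scores, dtype=float)
    if values.size == 0:
        raise ValueError("cannot tabulate percentiles of an empty score vector")
    direction = Direction(direction)
    out: dict[float, float] = {}
    for level in levels:
        q = level / 100.0
        if direction is Direction.LOWER_BETTER:
            q = 1.0 - q
        out[float(level)] = round_half_away(
            float(np.quantile(values, q, method="linear")), ndigits
        )
    return out


def es_cut_values(
    scores: Sequence[float],
    outer_limit: float,
    spec: ESBandSpec = ESBandSpec(),
    direction: Direction = Direction.HIGHER_BETTER,
    ndigits: int = 1,
) -> Tuple[float, float, float, float]:
    """The four ES band boundaries (ES0/1 .. ES3/4) from the impaired tail.

    ES0/1 is the outer tolerance limit; the others are the scores' empirical
    quantiles at the cumulative rank proportions, counted from the impaired
    tail, rounded to ``ndigits``.
    """
    values = np.asarray(scores, dtype=float)
    if values.size == 0:
        raise ValueError("cannot build ES bands from an empty score vector")
    direction = Direction(direction)
    cuts = [round_half_away(float(outer_limit), ndigits)]
    for prop in spec.cuts:
        q = prop if direction is Direction.HIGHER_BETTER else 1.0 - prop
        cuts.append(round_half_away(float(np.quantile(values, q, method="linear")), ndigits))
    return tuple(cuts)


def es_band_intervals(
    es_cuts: Tuple[float, float, float, float], direction: Direction
) -> list[tuple[int, float, float]]:
    """The 5 labelled half-open bands as (label, impaired_edge, better_edge).

    Edges run from the impaired tail outward; infinite edges mark the open
    ends.  Purely descriptive - membership tests live in ``scoring.to_es``.
    """
    inf = float("inf")
    c0, c1, c2, c3 = es_cuts
    if Direction(direction) is Direction.HIGHER_BETTER:
        return [(0, -inf, c0), (1, c0, c1), (2, c1, c2), (3, c2, c3), (4, c3, inf)]
    return [(0, inf, c0), (1, c0, c1), (2, c1, c2), (3, c2, c3), (4, c3, -inf)]
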