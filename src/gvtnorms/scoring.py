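"""Clinical scoring engine: raw scoresheet -> corrected scores, percentile, ES.

Scoring runs in five steps: (1) count correctly followed lines (accuracy
0-10); (2) add the per-line uniformization corrections to the execution times
of the correct lines; (3) average those adjusted times; (4) add the
demographic adjustment for age, education and sex (accuracy) or age (time);
(5) look the corrected scores up in the percentile table, the equivalent-score
bands, and the tolerance limits.

Rounding is half-away-from-zero to one decimal and is applied only to the
final demographic adjustment and the final mean corrected time, never to
intermediates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

from .types import (
    LINE_IDS,
    AdjustmentModel,
    Classification,
    Direction,
    LineCorrectionTable,
    LineId,
    Measure,
    NormScales,
    ParticipantRecord,
    PercentileResult,
    Predictor,
    ScoredResult,
    Sex,
    round_half_away,
)


@dataclass(frozen=True)
class Band:
    """A demographic band with the representative value entered in the regression."""

    lo: float
    hi: float  # inclusive; math.inf for an open-ended band
    representative: float
    label: str

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi


#: Decade bands with their midpoints (e.g. 20-29 -> 24.5), as used in the grids.
AGE_BANDS: Tuple[Band, ...] = tuple(
    Band(lo, lo + 9, lo + 4.5, f"{lo}-{lo + 9}") for lo in range(20, 80, 10)
)

#: Education bands of the correction grid.  Representatives 2.5 / 7 / 11 are
#: the interval midpoints; the open-ended ">13" band uses 16.2, the value that
#: regenerates the published grid column exactly (midpoints are undefined for
#: an open band; 16.2 is consistent with the band's mean schooling in a cohort
#: whose education tops out in the low twenties).
EDUCATION_BANDS: Tuple[Band, ...] = (
    Band(0, 5, 2.5, "0-5"),
    Band(6, 8, 7.0, "6-8"),
    Band(9, 13, 11.0, "9-13"),
    Band(14, math.inf, 16.2, ">13"),
)

#: Age range on which the norms are defined.
NORM_AGE_RANGE = (20, 79)


def find_band(bands: Sequence[Band], x: float) -> Band:
    """Band containing ``x``; values outside all bands clamp to the nearest."""
    for band in bands:
        if band.contains(x):
            return band
    return bands[0] if x < bands[0].lo else bands[-1]


def score_accuracy(record: ParticipantRecord) -> int:
    """Number of lines followed correctly (0-10)."""
    return sum(1 for lid in LINE_IDS if record.outcomes[lid].correct)


def apply_line_corrections(
    record: ParticipantRecord, table: LineCorrectionTable
) -> dict[LineId, float]:
    """Raw time + per-line correction, for the correctly followed lines only."""
    return {
        lid: time + table.correction_s[lid]
        for lid, time in record.valid_times().items()
    }


def mean_corrected_time(adjusted: Mapping[LineId, float]) -> float:
    """Mean of the adjusted times, rounded half-away-from-zero to 1 decimal.

    Raises ``ValueError`` when no line was followed correctly; callers then
    report accuracy only.
    """
    if not adjusted:
        raise ValueError("mean corrected time undefined: no valid lines")
    return round_half_away(sum(adjusted.values()) / len(adjusted), 1)


def demographic_adjustment(
    model: AdjustmentModel,
    age: float,
    education: float,
    sex: int,
    mode: str = "banded",
    age_bands: Sequence[Band] = AGE_BANDS,
    education_bands: Sequence[Band] = EDUCATION_BANDS,
) -> float:
    """Demographic correction for one participant, rounded to 1 decimal.

    ``banded`` mode (the default, and the mode behind the published grids)
    replaces age by its decade midpoint and education by its band
    representative before evaluating the model; ``exact`` mode uses the
    continuous values.
    """
    if mode not in ("banded", "exact"):
        raise ValueError(f"mode must be 'banded' or 'exact', got {mode!r}")
    if mode == "banded":
        age = find_band(age_bands, age).representative
        education = find_band(education_bands, education).representative
    values = {
        Predictor.AGE: float(age),
        Predictor.EDUCATION: float(education),
        Predictor.SEX: float(Sex(sex).value),
    }
    return round_half_away(model.evaluate(values), 1)


def _meets(x: float, value: float, direction: Direction) -> bool:
    """Does score ``x`` reach the performance level of ``value``?"""
    if direction is Direction.HIGHER_BETTER:
        return x >= value - 1e-9
    return x <= value + 1e-9


def to_percentile(corrected: float, scales: NormScales) -> PercentileResult:
    """Tabulated percentile of a corrected score, or the bracketing interval.

    Scores beyond the table extremes clamp to "<lowest" / ">highest".
    Comparison happens at the table's one-decimal resolution.
    """
    if not scales.percentiles:
        raise ValueError("percentile table is empty")
    levels = sorted(scales.percentiles)
    x = round_half_away(corrected, 1)
    exact = [
        lv
        for lv in levels
        if abs(round_half_away(scales.percentiles[lv], 1) - x) < 1e-9
    ]
    if exact:
        return PercentileResult(exact[-1], exact[-1])
    met = [lv for lv in levels if _meets(x, scales.percentiles[lv], scales.direction)]
    if not met:
        return PercentileResult(None, levels[0])
    best = met[-1]
    if best == levels[-1]:
        return PercentileResult(levels[-1], None)
    nxt = levels[levels.index(best) + 1]
    return PercentileResult(best, nxt)


def to_es(corrected: float, scales: NormScales) -> int:
    """Equivalent score 0-4 of a corrected score.

    ES0 is at-or-beyond the outer tolerance limit (inclusive toward
    impairment, matching the published ``<=1.6`` / ``>=37.4`` bands); the
    remaining boundaries belong to the band on the lower-valued side, which
    reproduces the printed band edges on both scales.
    """
    c0, c1, c2, c3 = scales.es_cuts
    eps = 1e-9
    if scales.direction is Direction.HIGHER_BETTER:
        if corrected <= c0 + eps:
            return 0
        if corrected <= c1 + eps:
            return 1
        if corrected <= c2 + eps:
            return 2
        if corrected <= c3 + eps:
            return 3
        return 4
    if corrected >= c0 - eps:
        return 0
    if corrected > c1 + eps:
        return 1
    if corrected > c2 + eps:
        return 2
    if corrected > c3 + eps:
        return 3
    return 4


def classify(corrected: float, scales: NormScales) -> Classification:
    """Impaired / uncertain / normal-range relative to the tolerance limits.

    Scores at or beyond the outer limit (toward impairment) are impaired;
    scores from there up to and including the inner limit are uncertain.
    """
    eps = 1e-9
    if scales.direction is Direction.HIGHER_BETTER:
        if corrected <= scales.tolerance_outer + eps:
            return Classification.IMPAIRED
        if corrected <= scales.tolerance_inner + eps:
            return Classification.UNCERTAIN
        return Classification.NORMAL
    if corrected >= scales.tolerance_outer - eps:
        return Classification.IMPAIRED
    if corrected >= scales.tolerance_inner - eps:
        return Classification.UNCERTAIN
    return Classification.NORMAL


def score_record(
    record: ParticipantRecord,
    line_corrections: LineCorrectionTable,
    models: Mapping[Measure, AdjustmentModel],
    scales: Mapping[Measure, NormScales],
    mode: str = "banded",
) -> ScoredResult:
    """Score one participant end to end against a norm set."""
    raw_acc = score_accuracy(record)
    corr_acc = demographic_adjustment(
        models[Measure.ACCURACY], record.age, record.education, record.sex, mode=mode
    )
    corrected_acc = round_half_away(raw_acc + corr_acc, 1)
    acc_scales = scales[Measure.ACCURACY]
    lo, hi = NORM_AGE_RANGE
    result = ScoredResult(
        id=record.id,
        raw_accuracy=raw_acc,
        demographic_correction_accuracy=corr_acc,
        corrected_accuracy=corrected_acc,
        percentile_accuracy=to_percentile(corrected_acc, acc_scales),
        es_accuracy=to_es(corrected_acc, acc_scales),
        classification_accuracy=classify(corrected_acc, acc_scales),
        extrapolated=not (lo <= record.age <= hi),
    )
    if raw_acc == 0:
        return result  # execution time not assessable
    adjusted = apply_line_corrections(record, line_corrections)
    result.adjusted_line_times = adjusted
    result.mean_corrected_time = mean_corrected_time(adjusted)
    corr_time = demographic_adjustment(
        models[Measure.TIME], record.age, record.education, record.sex, mode=mode
    )
    result.demographic_correction_time = corr_time
    result.corrected_time = round_half_away(result.mean_corrected_time + corr_time, 1)
    time_scales = scales[Measure.TIME]
    result.percentile_time = to_percentile(result.corrected_time, time_scales)
    result.es_time = to_es(result.corrected_time, time_scales)
    result.classification_time = classify(result.corrected_time, time_scales)
    return result
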