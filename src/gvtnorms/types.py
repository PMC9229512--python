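"""Domain types for Groffman Visual Tracing (GVT) scoring and norm derivation.

The GVT test presents two cards (A and B), each with five intertwined lines
(A-E).  A participant follows each line with the eyes only; a line is scored
correct (1) or not (0), and the execution time in seconds is recorded only
for correctly followed lines.  The test yields two measures: accuracy
(0-10 lines correct) and a mean corrected execution time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence, Tuple

CARDS = ("A", "B")
LINES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True, order=True)
class LineId:
    """One of the ten card/line positions, ordered card A lines A-E then card B."""

    card: str
    line: str

    def __post_init__(self) -> None:
        if self.card not in CARDS:
            raise ValueError(f"card must be one of {CARDS}, got {self.card!r}")
        if self.line not in LINES:
            raise ValueError(f"line must be one of {LINES}, got {self.line!r}")

    def __str__(self) -> str:
        return f"{self.card}_{self.line}"

    @classmethod
    def parse(cls, text: str) -> "LineId":
        card, _, line = text.partition("_")
        return cls(card, line)


#: All ten line identifiers in canonical order.
LINE_IDS: Tuple[LineId, ...] = tuple(
    LineId(card, line) for card in CARDS for line in LINES
)


@dataclass(frozen=True)
class LineOutcome:
    """Outcome of a single line: correct flag, and time only when correct."""

    correct: bool
    time_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.correct:
            if self.time_s is None:
                raise ValueError("a correct line must carry an execution time")
            if not self.time_s > 0:
                raise ValueError(f"time_s must be > 0, got {self.time_s}")
        elif self.time_s is not None:
            raise ValueError("an incorrect line must not carry an execution time")


class Sex(int, Enum):
    """Sex coding used throughout: female 0, male 1."""

    F = 0
    M = 1

    @classmethod
    def parse(cls, text) -> "Sex":
        if isinstance(text, Sex):
            return text
        s = str(text).strip().upper()
        if s in ("F", "FEMALE", "0"):
            return cls.F
        if s in ("M", "MALE", "1"):
            return cls.M
        raise ValueError(f"cannot parse sex from {text!r}")


@dataclass
class ParticipantRecord:
    """Demographics plus the ten per-line outcomes of one scoresheet."""

    id: str
    age: int
    education: int
    sex: Sex
    outcomes: Mapping[LineId, LineOutcome]

    def __post_init__(self) -> None:
        if self.education < 0:
            raise ValueError("education must be >= 0 years")
        missing = [str(l) for l in LINE_IDS if l not in self.outcomes]
        if missing:
            raise ValueError(f"outcomes missing line ids: {missing}")
        self.sex = Sex(self.sex)

    def valid_times(self) -> dict[LineId, float]:
        """Raw execution times of the correctly followed lines."""
        return {
            lid: out.time_s
            for lid, out in ((l, self.outcomes[l]) for l in LINE_IDS)
            if out.correct
        }


@dataclass(frozen=True)
class LineCorrectionTable:
    """Additive per-line seconds making mean line times uniform (first correction)."""

    correction_s: Mapping[LineId, float]

    def __post_init__(self) -> None:
        missing = [str(l) for l in LINE_IDS if l not in self.correction_s]
        if missing:
            raise ValueError(f"correction table missing line ids: {missing}")

    def rounded(self, ndigits: int = 1) -> "LineCorrectionTable":
        return LineCorrectionTable(
            {lid: round_half_away(v, ndigits) for lid, v in self.correction_s.items()}
        )


class TransformFamily(str, Enum):
    """Predictor transformations searched during norm derivation."""

    LINEAR = "linear"
    REVERSE = "reverse"
    QUADRATIC = "quadratic"
    LOGARITHMIC = "logarithmic"
    LOGARITHMIC_REVERSE = "logarithmic_reverse"
    SQUARE_ROOT = "square_root"
    GEOMETRICAL = "geometrical"
    INVERSE = "inverse"
    EXPONENTIAL = "exponential"


#: Fixed family order used for deterministic tie-breaking.
FAMILY_ORDER = tuple(TransformFamily)


@dataclass(frozen=True)
class TransformSpec:
    """A transformation of one predictor.

    ``shift_constant`` is the k of the reverse families (k - x, log(k - x));
    ``scale_constant`` is the s of the exponential family exp(x / s).
    """

    family: TransformFamily
    shift_constant: Optional[float] = None
    scale_constant: Optional[float] = None

    def __post_init__(self) -> None:
        fam = TransformFamily(self.family)
        object.__setattr__(self, "family", fam)
        if fam in (TransformFamily.REVERSE, TransformFamily.LOGARITHMIC_REVERSE):
            if self.shift_constant is None:
                raise ValueError(f"{fam.value} transform requires shift_constant k")
        if fam is TransformFamily.EXPONENTIAL and (
            self.scale_constant is None or self.scale_constant <= 0
        ):
            raise ValueError("exponential transform requires scale_constant > 0")

    def apply(self, x: float) -> float:
        fam = self.family
        if fam is TransformFamily.LINEAR:
            return float(x)
        if fam is TransformFamily.REVERSE:
            return self.shift_constant - x
        if fam is TransformFamily.QUADRATIC:
            return float(x) ** 2
        if fam is TransformFamily.LOGARITHMIC:
            if x <= 0:
                raise ValueError(f"logarithm of non-positive predictor {x}")
            return math.log(x)
        if fam is TransformFamily.LOGARITHMIC_REVERSE:
            if x >= self.shift_constant:
                raise ValueError(
                    f"predictor {x} >= shift constant {self.shift_constant}"
                )
            return math.log(self.shift_constant - x)
        if fam is TransformFamily.SQUARE_ROOT:
            if x < 0:
                raise ValueError(f"square root of negative predictor {x}")
            return math.sqrt(x)
        if fam is TransformFamily.GEOMETRICAL:
            return float(x) ** 3
        if fam is TransformFamily.INVERSE:
            if x == 0:
                raise ValueError("inverse transform undefined at 0")
            return 1.0 / x
        if fam is TransformFamily.EXPONENTIAL:
            return math.exp(x / self.scale_constant)
        raise AssertionError(fam)


class Predictor(str, Enum):
    AGE = "age"
    EDUCATION = "education"
    SEX = "sex"


class Measure(str, Enum):
    ACCURACY = "accuracy"
    TIME = "time"


@dataclass(frozen=True)
class ModelTerm:
    """One term of a demographic adjustment model."""

    predictor: Predictor
    transform: TransformSpec
    coefficient: float
    #: sample mean of the transformed predictor in the normative cohort
    centering_constant: float


@dataclass(frozen=True)
class AdjustmentModel:
    """Demographic adjustment: sum of coefficient * (transform(x) - centering).

    Coefficients are the reversed-sign regression coefficients, so ADDING the
    adjustment to a raw score removes the estimated demographic effect.  The
    adjustment is exactly 0 for a participant whose transformed predictors
    equal the centering constants.
    """

    measure: Measure
    terms: Tuple[ModelTerm, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "measure", Measure(self.measure))

    def predictors(self) -> Tuple[Predictor, ...]:
        return tuple(t.predictor for t in self.terms)

    def evaluate(self, values: Mapping[Predictor, float]) -> float:
        """Unrounded adjustment at the given predictor values."""
        total = 0.0
        for term in self.terms:
            x = values[term.predictor]
            total += term.coefficient * (term.transform.apply(x) - term.centering_constant)
        return total


class Direction(str, Enum):
    """Which end of the score scale is better performance."""

    HIGHER_BETTER = "higher_better"
    LOWER_BETTER = "lower_better"


class Classification(str, Enum):
    IMPAIRED = "impaired"
    UNCERTAIN = "uncertain"
    NORMAL = "normal-range"


@dataclass(frozen=True)
class NormScales:
    """Clinical scales for one measure: tolerance limits, percentiles, ES bands.

    ``es_cuts`` are the four band boundaries ordered from the impaired tail:
    ES0/1 (the outer tolerance limit), ES1/2, ES2/3, ES3/4 (the median).
    ``grid`` maps band labels to rounded corrections:
    ``(age_band, education_band, sex_label)`` for accuracy, ``age_band`` for time.
    """

    measure: Measure
    direction: Direction
    tolerance_outer: float
    tolerance_inner: float
    percentiles: Mapping[float, float]
    es_cuts: Tuple[float, float, float, float]
    grid: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "measure", Measure(self.measure))
        object.__setattr__(self, "direction", Direction(self.direction))
        object.__setattr__(self, "es_cuts", tuple(self.es_cuts))
        if len(self.es_cuts) != 4:
            raise ValueError("es_cuts must hold the 4 ES band boundaries")
        lo_is_bad = self.direction is Direction.HIGHER_BETTER
        # outer limit is at or beyond the impaired side of the inner limit
        if lo_is_bad and self.tolerance_outer > self.tolerance_inner:
            raise ValueError("outer tolerance limit must be <= inner for this scale")
        if not lo_is_bad and self.tolerance_outer < self.tolerance_inner:
            raise ValueError("outer tolerance limit must be >= inner for this scale")


@dataclass(frozen=True)
class PercentileResult:
    """A tabulated percentile level, a bracketing interval, or an open extreme.

    ``lo == hi`` for an exact table hit; ``lo is None`` means below the lowest
    tabulated level ("<1"); ``hi is None`` means above the highest (">99").
    """

    lo: Optional[float]
    hi: Optional[float]

    def __str__(self) -> str:
        if self.lo is None:
            return f"<{_fmt_level(self.hi)}"
        if self.hi is None:
            return f">{_fmt_level(self.lo)}"
        if self.lo == self.hi:
            return _fmt_level(self.lo)
        return f"{_fmt_level(self.lo)}-{_fmt_level(self.hi)}"

    @property
    def is_exact(self) -> bool:
        return self.lo is not None and self.lo == self.hi


def _fmt_level(level: float) -> str:
    return str(int(level)) if float(level).is_integer() else str(level)


@dataclass
class ScoredResult:
    """Full scoring of one participant against a norm set."""

    id: str
    raw_accuracy: int
    demographic_correction_accuracy: float
    corrected_accuracy: float
    percentile_accuracy: PercentileResult
    es_accuracy: int
    classification_accuracy: Classification
    adjusted_line_times: dict[LineId, float] = field(default_factory=dict)
    mean_corrected_time: Optional[float] = None
    demographic_correction_time: Optional[float] = None
    corrected_time: Optional[float] = None
    percentile_time: Optional[PercentileResult] = None
    es_time: Optional[int] = None
    classification_time: Optional[Classification] = None
    extrapolated: bool = False


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (21.35 -> 21.4, -1.15 -> -1.2).

    A 1e-9 guard absorbs binary representation error so that values that are
    exact halves in decimal (e.g. 213.5/10) round as written.
    """
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5 + 1e-9), x) / scale


def mean_of(values: Sequence[float]) -> float:
    if not values:
        raise ValueError("mean of empty sequence")
    return sum(values) / len(values)
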