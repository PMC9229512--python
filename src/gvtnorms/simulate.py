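"""Synthetic GVT cohorts with the demographic and performance structure the
norm-derivation pipeline assumes.

A cohort is drawn from a joint age-decade x education-band x sex table (the
default mirrors the normative sample's composition: n = 526, mean age about
46 years, 56% female).  Per-line correctness is Bernoulli on the logit scale
with a participant-level latent ability factor and demographic effects whose
size is specified on the MEASURE scale (expected accuracy points per unit of
the transformed predictor), so the generating adjustment model is known
exactly.  Execution times are log-normal per line (right skew, hard floor)
with a shared participant speed factor and an additive age effect in seconds,
again making the generating time adjustment model exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

from .derivation import outlier_threshold
from .types import (
    LINE_IDS,
    AdjustmentModel,
    LineId,
    LineOutcome,
    Measure,
    ModelTerm,
    ParticipantRecord,
    Predictor,
    Sex,
    TransformFamily,
    TransformSpec,
)

#: Joint demographic counts of the reference normative sample
#: (decade, education band, sex) -> participants.
DEFAULT_DEMOGRAPHIC_TABLE: dict[tuple[str, str, str], int] = {}
_T1 = {
    "0-5": {"20-29": (0, 0), "30-39": (0, 0), "40-49": (0, 1),
            "50-59": (0, 0), "60-69": (0, 1), "70-79": (4, 2)},
    "6-8": {"20-29": (0, 0), "30-39": (3, 6), "40-49": (5, 5),
            "50-59": (11, 10), "60-69": (11, 6), "70-79": (9, 12)},
    "9-13": {"20-29": (16, 12), "30-39": (18, 20), "40-49": (21, 16),
             "50-59": (26, 19), "60-69": (21, 15), "70-79": (6, 9)},
    ">13": {"20-29": (47, 27), "30-39": (33, 21), "40-49": (29, 24),
            "50-59": (21, 14), "60-69": (8, 8), "70-79": (3, 6)},
}
for _edu, _row in _T1.items():
    for _dec, (_f, _m) in _row.items():
        DEFAULT_DEMOGRAPHIC_TABLE[(_dec, _edu, "F")] = _f
        DEFAULT_DEMOGRAPHIC_TABLE[(_dec, _edu, "M")] = _m

#: Reference per-line marginal success probabilities (valid counts / 526).
DEFAULT_LINE_VALID_P: dict[LineId, float] = {
    lid: c / 526.0
    for lid, c in zip(
        LINE_IDS, (354, 317, 268, 255, 392, 369, 336, 386, 302, 231)
    )
}

#: Reference per-line mean execution times in seconds.
DEFAULT_LINE_MEAN_S: dict[LineId, float] = {
    lid: m
    for lid, m in zip(
        LINE_IDS, (18.3, 22.9, 28.7, 22.9, 19.4, 16.4, 20.7, 21.3, 23.6, 25.7)
    )
}

#: Integer years of schooling sampled within each education band; the
#: reference sample's education spans 5-25 years, so the 0-5 band bottoms
#: out at 5.
DEFAULT_EDUCATION_VALUES: dict[str, Tuple[int, ...]] = {
    "0-5": (5,),
    "6-8": (6, 7, 8),
    "9-13": (9, 10, 11, 12, 13),
    ">13": tuple(range(14, 23)),
}

_DECADE_LO = {"20-29": 20, "30-39": 30, "40-49": 40,
              "50-59": 50, "60-69": 60, "70-79": 70}

AGE_SQ = TransformSpec(TransformFamily.QUADRATIC)
EDU_INV = TransformSpec(TransformFamily.INVERSE)
SEX_LIN = TransformSpec(TransformFamily.LINEAR)
LOG_REVERSE_AGE = TransformSpec(TransformFamily.LOGARITHMIC_REVERSE, shift_constant=86.9)


@dataclass
class SyntheticCohortConfig:
    """Generating distributions and effect sizes for a synthetic cohort.

    Demographic effects are expressed as expected raw-score change per unit
    of the transformed predictor, matching the published adjustment
    equations' magnitudes with reversed sign (the adjustment undoes the
    effect): accuracy loses 0.000597 points per year-squared of age and
    16.77 points per unit 1/education and gains 0.455 points for males;
    mean execution time falls 4.364 s per unit log(86.9 - age).
    """

    n: int = 526
    seed: int = 0
    demographic_table: Mapping[tuple[str, str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHIC_TABLE)
    )
    education_values: Mapping[str, Tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_EDUCATION_VALUES)
    )
    line_valid_p: Mapping[LineId, float] = field(
        default_factory=lambda: dict(DEFAULT_LINE_VALID_P)
    )
    line_mean_s: Mapping[LineId, float] = field(
        default_factory=lambda: dict(DEFAULT_LINE_MEAN_S)
    )
    #: measure-scale effects on accuracy: {predictor: (transform, effect)}
    accuracy_effects: Mapping[Predictor, Tuple[TransformSpec, float]] = field(
        default_factory=lambda: {
            Predictor.AGE: (AGE_SQ, -0.000597),
            Predictor.EDUCATION: (EDU_INV, -16.77),
            Predictor.SEX: (SEX_LIN, 0.455),
        }
    )
    #: measure-scale effects on mean execution time
    time_effects: Mapping[Predictor, Tuple[TransformSpec, float]] = field(
        default_factory=lambda: {Predictor.AGE: (LOG_REVERSE_AGE, -4.364)}
    )
    ability_sd: float = 0.75  # participant latent accuracy factor, logit scale
    time_sigma_participant: float = 0.30  # shared speed factor, log scale
    time_sigma_line: float = 0.31  # residual per line, log scale
    truncation_s: Tuple[float, float] = (5.0, 200.0)
    outlier_rate: float = 0.0
    outlier_time_s: Tuple[float, float] = (80.0, 150.0)

    def __post_init__(self) -> None:
        counts = list(self.demographic_table.values())
        if any(c < 0 for c in counts) or sum(counts) <= 0:
            raise ValueError("demographic table must be nonnegative with positive total")
        lo, hi = self.truncation_s
        if not (0 < lo < hi <= 200):
            raise ValueError("truncation bounds must satisfy 0 < lo < hi <= 200")
        missing = [str(l) for l in LINE_IDS if l not in self.line_mean_s]
        if missing:
            raise ValueError(f"line_mean_s missing line ids: {missing}")


# ---------------------------------------------------------------------------
# exact enumeration of the demographic distribution
# ---------------------------------------------------------------------------

def _demographic_atoms(
    config: SyntheticCohortConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(weights, ages, educations, sexes) enumerating the sampling distribution:
    cells from the joint table, ages uniform over the decade's integers,
    education uniform over the band's values."""
    w, ages, edus, sexes = [], [], [], []
    total = sum(config.demographic_table.values())
    for (dec, eduband, sex), count in config.demographic_table.items():
        if count == 0:
            continue
        lo = _DECADE_LO[dec]
        evals = config.education_values[eduband]
        cell_w = count / total / (10 * len(evals))
        for a in range(lo, lo + 10):
            for e in evals:
                w.append(cell_w)
                ages.append(a)
                edus.append(e)
                sexes.append(0 if sex == "F" else 1)
    return (np.array(w), np.array(ages, float),
            np.array(edus, float), np.array(sexes, float))


def _predictor_arrays(
    ages: np.ndarray, edus: np.ndarray, sexes: np.ndarray
) -> dict[Predictor, np.ndarray]:
    return {Predictor.AGE: ages, Predictor.EDUCATION: edus, Predictor.SEX: sexes}


def population_transform_means(
    config: SyntheticCohortConfig,
    effects: Mapping[Predictor, Tuple[TransformSpec, float]],
) -> dict[Predictor, float]:
    """Expected transformed-predictor values under the sampling distribution."""
    w, ages, edus, sexes = _demographic_atoms(config)
    arrays = _predictor_arrays(ages, edus, sexes)
    out = {}
    for pred, (spec, _) in effects.items():
        t = np.array([spec.apply(v) for v in arrays[pred]])
        out[pred] = float(np.sum(w * t))
    return out


def _measure_deviation(
    config: SyntheticCohortConfig,
    effects: Mapping[Predictor, Tuple[TransformSpec, float]],
    ages: np.ndarray, edus: np.ndarray, sexes: np.ndarray,
    means: Mapping[Predictor, float],
) -> np.ndarray:
    """Demographic effect on the measure scale, centered at the population."""
    arrays = _predictor_arrays(ages, edus, sexes)
    d = np.zeros_like(ages, dtype=float)
    for pred, (spec, effect) in effects.items():
        t = np.array([spec.apply(v) for v in arrays[pred]])
        d += effect * (t - means[pred])
    return d


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(21)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _effects_key(effects: Mapping[Predictor, Tuple[TransformSpec, float]]):
    return tuple(
        (p.value, s.family.value, s.shift_constant, s.scale_constant, e)
        for p, (s, e) in sorted(effects.items())
    )


def _calibration_key(config: SyntheticCohortConfig):
    return (
        tuple(sorted(config.demographic_table.items())),
        tuple(sorted((k, tuple(v)) for k, v in config.education_values.items())),
        tuple(config.line_valid_p[lid] for lid in LINE_IDS),
        _effects_key(config.accuracy_effects),
        config.ability_sd,
    )


_CALIBRATION_CACHE: dict = {}


@dataclass(frozen=True)
class _AccuracyCalibration:
    """Per-line logit intercepts plus the inverse marginal mean function.

    Demographic effects are configured on the MEASURE scale (expected
    accuracy points).  A measure-scale deviation d enters each line's logit
    as a common shift s(d) chosen so that the marginal expected score
    (integrating the latent ability) equals the baseline score plus d
    exactly: s(d) = f^{-1}(f(0) + d), where f is the marginal mean function
    of the common shift.  This makes the generating adjustment model exact
    rather than a first-order approximation.
    """

    intercepts: Tuple[float, ...]  # per line, canonical order
    s_grid: np.ndarray
    f_grid: np.ndarray  # marginal E[score] at each s
    f0: float

    def shift(self, d: np.ndarray | float) -> np.ndarray | float:
        target = np.clip(self.f0 + d, self.f_grid[0], self.f_grid[-1])
        return np.interp(target, self.f_grid, self.s_grid)


def _calibrate_accuracy(config: SyntheticCohortConfig) -> _AccuracyCalibration:
    """Solve the per-line intercepts and the mean-function inversion.

    Intercepts make each line's MARGINAL success probability (integrating
    both the latent ability and the demographic mixture) match the
    configured target; the fixed point between intercepts and the shift
    function converges in a few sweeps.  Deterministic, hence cached.
    """
    key = _calibration_key(config)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    w, ages, edus, sexes = _demographic_atoms(config)
    means = population_transform_means(config, config.accuracy_effects)
    d = _measure_deviation(config, config.accuracy_effects, ages, edus, sexes, means)
    z = _GH_NODES * config.ability_sd  # (q,)
    wq = _GH_WEIGHTS
    targets = np.array([config.line_valid_p[lid] for lid in LINE_IDS])
    s_grid = np.linspace(-12.0, 12.0, 2401)

    def solve_intercepts(s_atoms: np.ndarray) -> np.ndarray:
        # vectorized bisection over the 10 lines
        grid = s_atoms[:, None] + z[None, :]  # (m, q)
        ww = w[:, None] * wq[None, :]
        lo = np.full(10, -12.0)
        hi = np.full(10, 12.0)
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            marg = np.einsum("mq,mql->l", ww, _expit(mid[None, None, :] + grid[:, :, None]))
            too_low = marg < targets
            lo = np.where(too_low, mid, lo)
            hi = np.where(too_low, hi, mid)
        return 0.5 * (lo + hi)

    a = solve_intercepts(np.zeros_like(d))
    calib = None
    for _ in range(3):
        # marginal mean function of the common shift, ability integrated out
        f = np.zeros_like(s_grid)
        for ai in a:
            f += np.sum(wq[None, :] * _expit(s_grid[:, None] + ai + z[None, :]), axis=1)
        f0 = float(np.interp(0.0, s_grid, f))
        calib = _AccuracyCalibration(tuple(a), s_grid, f, f0)
        a = solve_intercepts(np.asarray(calib.shift(d)))
    calib = _AccuracyCalibration(tuple(a), s_grid, calib.f_grid, calib.f0)
    # rebuild f with the final intercepts so shift() and intercepts agree
    f = np.zeros_like(s_grid)
    for ai in a:
        f += np.sum(wq[None, :] * _expit(s_grid[:, None] + ai + z[None, :]), axis=1)
    calib = _AccuracyCalibration(tuple(a), s_grid, f, float(np.interp(0.0, s_grid, f)))
    _CALIBRATION_CACHE[key] = calib
    return calib


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_cohort(
    config: SyntheticCohortConfig, seed: Optional[int] = None
) -> list[ParticipantRecord]:
    """Draw a reproducible synthetic cohort; same seed, same cohort."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cells = [(k, c) for k, c in config.demographic_table.items() if c > 0]
    if not cells:
        raise ValueError("demographic table is empty")
    probs = np.array([c for _, c in cells], dtype=float)
    probs /= probs.sum()
    calib = _calibrate_accuracy(config)
    intercepts = dict(zip(LINE_IDS, calib.intercepts))
    acc_means = population_transform_means(config, config.accuracy_effects)
    time_means = population_transform_means(config, config.time_effects)
    sigma_tot_sq = config.time_sigma_participant ** 2 + config.time_sigma_line ** 2
    lo_t, hi_t = config.truncation_s

    cohort: list[ParticipantRecord] = []
    cell_idx = rng.choice(len(cells), size=config.n, p=probs)
    for i in range(config.n):
        (dec, eduband, sexlab), _ = cells[cell_idx[i]]
        age = int(rng.integers(_DECADE_LO[dec], _DECADE_LO[dec] + 10))
        education = int(rng.choice(config.education_values[eduband]))
        sex = Sex.F if sexlab == "F" else Sex.M
        ages = np.array([age], float)
        edus = np.array([education], float)
        sexes = np.array([float(sex.value)], float)
        d_acc = _measure_deviation(
            config, config.accuracy_effects, ages, edus, sexes, acc_means
        )[0]
        d_time = _measure_deviation(
            config, config.time_effects, ages, edus, sexes, time_means
        )[0]
        ability = rng.normal(0.0, config.ability_sd)
        speed = rng.normal(0.0, config.time_sigma_participant)
        shift = float(calib.shift(d_acc))
        outcomes: dict[LineId, LineOutcome] = {}
        for lid in LINE_IDS:
            eta = intercepts[lid] + shift + ability
            correct = rng.random() < 1.0 / (1.0 + math.exp(-eta))
            if not correct:
                outcomes[lid] = LineOutcome(False)
                continue
            log_s = (
                math.log(config.line_mean_s[lid])
                - sigma_tot_sq / 2.0
                + speed
                + rng.normal(0.0, config.time_sigma_line)
            )
            t = math.exp(log_s) + d_time
            outcomes[lid] = LineOutcome(True, float(np.clip(t, lo_t, hi_t)))
        record = ParticipantRecord(
            id=f"S{i + 1:04d}", age=age, education=education, sex=sex,
            outcomes=outcomes,
        )
        if config.outlier_rate > 0 and rng.random() < config.outlier_rate:
            _inflate_one_line(record, rng, config.outlier_time_s)
        cohort.append(record)
    return cohort


def _inflate_one_line(
    record: ParticipantRecord, rng: np.random.Generator,
    time_range: Tuple[float, float],
) -> bool:
    """Replace one valid line's time with an inflated value; False if no valid line."""
    valid = [lid for lid in LINE_IDS if record.outcomes[lid].correct]
    if not valid:
        return False
    lid = valid[int(rng.integers(len(valid)))]
    t = float(rng.uniform(*time_range))
    record.outcomes = {**record.outcomes, lid: LineOutcome(True, t)}
    return True


def true_adjustments(
    config: SyntheticCohortConfig,
    cohort: Optional[Sequence[ParticipantRecord]] = None,
) -> tuple[AdjustmentModel, AdjustmentModel]:
    """The generating models re-expressed on the measure scale.

    Coefficients are the reversed generating effects (an adjustment undoes
    the effect).  Centering constants are the sample means of the transformed
    predictors when a cohort is given, otherwise their expectations under the
    sampling distribution.
    """
    def center(pred: Predictor, spec: TransformSpec, pop: Mapping[Predictor, float]) -> float:
        if cohort is None:
            return pop[pred]
        vals = {
            Predictor.AGE: lambda r: float(r.age),
            Predictor.EDUCATION: lambda r: float(r.education),
            Predictor.SEX: lambda r: float(r.sex.value),
        }[pred]
        return float(np.mean([spec.apply(vals(r)) for r in cohort]))

    models = []
    for measure, effects in (
        (Measure.ACCURACY, config.accuracy_effects),
        (Measure.TIME, config.time_effects),
    ):
        pop = population_transform_means(config, effects)
        terms = tuple(
            ModelTerm(
                predictor=pred,
                transform=spec,
                coefficient=-effect,
                centering_constant=center(pred, spec, pop),
            )
            for pred, (spec, effect) in effects.items()
        )
        models.append(AdjustmentModel(measure=measure, terms=terms))
    return models[0], models[1]


def make_filter_fixture(
    n: int = 537,
    n_offenders: int = 11,
    seed: int = 0,
    config: Optional[SyntheticCohortConfig] = None,
) -> tuple[list[ParticipantRecord], list[str]]:
    """Synthetic cohort with a known, exact number of extreme-outlier cases.

    Constructs ground truth for the case-wise deletion step: generates a
    clean cohort, pushes any naturally borderline times well below the
    pooled-time threshold, then plants one inflated time in each of
    ``n_offenders`` randomly chosen participants.  Returns the cohort and
    the planted participant ids.
    """
    if config is None:
        config = SyntheticCohortConfig(n=n, seed=seed)
    else:
        config = replace_n_seed(config, n, seed)
    rng = np.random.default_rng(seed + 1)
    cohort = generate_cohort(config)
    t0 = outlier_threshold(cohort)
    for i, rec in enumerate(cohort):
        vt = rec.valid_times()
        if any(t >= t0 - 5.0 for t in vt.values()):
            new = dict(rec.outcomes)
            for lid, t in vt.items():
                if t >= t0 - 5.0:
                    new[lid] = LineOutcome(True, float(rng.uniform(10.0, 30.0)))
            rec.outcomes = new
    t1 = outlier_threshold(cohort)
    eligible = [i for i, r in enumerate(cohort) if r.valid_times()]
    chosen = rng.choice(eligible, size=n_offenders, replace=False)
    planted: list[str] = []
    for i in sorted(int(j) for j in chosen):
        rec = cohort[i]
        valid = [lid for lid in LINE_IDS if rec.outcomes[lid].correct]
        lid = valid[int(rng.integers(len(valid)))]
        rec.outcomes = {
            **rec.outcomes,
            lid: LineOutcome(True, float(t1 + rng.uniform(10.0, 60.0))),
        }
        planted.append(rec.id)
    return cohort, planted


def replace_n_seed(
    config: SyntheticCohortConfig, n: int, seed: int
) -> SyntheticCohortConfig:
    import dataclasses

    return dataclasses.replace(config, n=n, seed=seed)
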