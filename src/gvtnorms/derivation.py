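"""Re-runnable norm-derivation pipeline.

Given a cohort of scoresheets the pipeline (a) deletes extreme-outlier cases
(any execution time at or above Q3 + 3*IQR of the pooled times removes the
whole participant), (b) computes the per-line uniformization corrections,
(c) searches nine transformations of each predictor by AICc in bivariate
regressions, (d) compares the 7 non-empty predictor subsets by AICc with
Akaike weights, (e) refits the winning model on deviations from the mean and
reverses the coefficients into an adjustment model, (f) tabulates the
correction grids, and (g) builds tolerance limits, percentiles and ES bands
from the corrected scores.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from . import scales as scales_mod
from .scoring import (
    AGE_BANDS,
    EDUCATION_BANDS,
    Band,
    apply_line_corrections,
)
from .types import (
    FAMILY_ORDER,
    LINE_IDS,
    AdjustmentModel,
    Direction,
    LineCorrectionTable,
    LineId,
    Measure,
    ModelTerm,
    NormScales,
    ParticipantRecord,
    Predictor,
    TransformFamily,
    TransformSpec,
    mean_of,
)

log = logging.getLogger(__name__)

REVERSE_FAMILIES = (TransformFamily.REVERSE, TransformFamily.LOGARITHMIC_REVERSE)

#: Shift offsets searched for the reverse families: k = max(x) + offset.
DEFAULT_K_OFFSETS: Tuple[float, ...] = tuple(range(1, 21))


# ---------------------------------------------------------------------------
# outlier filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierRule:
    """Extreme-outlier threshold: Q3 + multiplier * IQR of the pooled times."""

    multiplier: float = 3.0
    quantile_method: str = "linear"


def pooled_times(cohort: Sequence[ParticipantRecord]) -> np.ndarray:
    """All recorded execution times of all participants and lines."""
    times = [t for rec in cohort for t in rec.valid_times().values()]
    return np.asarray(times, dtype=float)


def outlier_threshold(
    cohort: Sequence[ParticipantRecord], rule: OutlierRule = OutlierRule()
) -> float:
    """Case-wise deletion threshold on the pooled execution times."""
    times = pooled_times(cohort)
    if times.size < 4:
        raise ValueError("need at least 4 recorded times to place quartiles")
    q1, q3 = np.quantile(times, [0.25, 0.75], method=rule.quantile_method)
    return float(q3 + rule.multiplier * (q3 - q1))


def filter_outlier_cases(
    cohort: Sequence[ParticipantRecord], threshold: float
) -> list[ParticipantRecord]:
    """Drop every participant with any time equal to or greater than the threshold."""
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    return [
        rec
        for rec in cohort
        if all(t < threshold for t in rec.valid_times().values())
    ]


# ---------------------------------------------------------------------------
# line uniformization
# ---------------------------------------------------------------------------

def line_correction_factors(
    cohort: Sequence[ParticipantRecord],
) -> LineCorrectionTable:
    """First correction: grand mean of the 10 line means minus each line mean.

    Computed from unrounded means, the entries sum exactly to zero and adding
    them equalizes every line's mean adjusted time.
    """
    means = line_means(cohort)
    grand = mean_of(list(means.values()))
    return LineCorrectionTable({lid: grand - m for lid, m in means.items()})


def line_means(cohort: Sequence[ParticipantRecord]) -> dict[LineId, float]:
    sums = {lid: 0.0 for lid in LINE_IDS}
    counts = {lid: 0 for lid in LINE_IDS}
    for rec in cohort:
        for lid, t in rec.valid_times().items():
            sums[lid] += t
            counts[lid] += 1
    empty = [str(l) for l in LINE_IDS if counts[l] == 0]
    if empty:
        raise ValueError(f"no valid execution times for lines: {empty}")
    return {lid: sums[lid] / counts[lid] for lid in LINE_IDS}


def corrections_from_line_means(means: Mapping[LineId, float]) -> LineCorrectionTable:
    """Correction table from already-computed line means (e.g. a printed table)."""
    grand = mean_of([means[lid] for lid in LINE_IDS])
    return LineCorrectionTable({lid: grand - means[lid] for lid in LINE_IDS})


def mean_corrected_times_unrounded(
    cohort: Sequence[ParticipantRecord], table: LineCorrectionTable
) -> dict[str, float]:
    """Participant -> unrounded mean of line-corrected times (valid lines only)."""
    out: dict[str, float] = {}
    for rec in cohort:
        adjusted = apply_line_corrections(rec, table)
        if adjusted:
            out[rec.id] = sum(adjusted.values()) / len(adjusted)
    return out


# ---------------------------------------------------------------------------
# information criteria and transformation search
# ---------------------------------------------------------------------------

def aicc(log_likelihood: float, K: int, n: int) -> float:
    """Small-sample corrected AIC: -2*LL + 2K + 2K(K+1)/(n-K-1)."""
    if n <= K + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={K + 1}")
    return -2.0 * log_likelihood + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


@dataclass(frozen=True)
class FittedCandidate:
    """A fitted regression entering a model comparison."""

    label: str
    log_likelihood: float
    K: int
    n: int


@dataclass(frozen=True)
class ModelComparisonRow:
    model_label: str
    K: int
    aicc: float
    delta_aicc: float
    model_likelihood: float
    weight: float
    log_likelihood: float
    cumulative_weight: float


def compare_models(candidates: Sequence[FittedCandidate]) -> list[ModelComparisonRow]:
    """AICc ranking with Akaike weights, sorted ascending by AICc.

    All candidates must be fitted on the same observations (same n).
    """
    if not candidates:
        raise ValueError("no candidate models to compare")
    ns = {c.n for c in candidates}
    if len(ns) > 1:
        raise ValueError(f"candidates fitted on different observation sets: n={sorted(ns)}")
    n = ns.pop()
    scored = [(aicc(c.log_likelihood, c.K, n), c) for c in candidates]
    scored.sort(key=lambda t: (round(t[0], 8), t[1].K, t[1].label))
    best = scored[0][0]
    liks = [math.exp(-(a - best) / 2.0) for a, _ in scored]
    total = sum(liks)
    rows, cum = [], 0.0
    for (a, c), lik in zip(scored, liks):
        w = lik / total
        cum += w
        rows.append(
            ModelComparisonRow(
                model_label=c.label,
                K=c.K,
                aicc=a,
                delta_aicc=a - best,
                model_likelihood=lik,
                weight=w,
                log_likelihood=c.log_likelihood,
                cumulative_weight=min(cum, 1.0),
            )
        )
    return rows


@dataclass(frozen=True)
class TransformFit:
    spec: TransformSpec
    aicc: float
    log_likelihood: float
    slope: float
    intercept: float


def _make_spec(
    family: TransformFamily,
    x: np.ndarray,
    k_offsets: Sequence[float],
) -> list[TransformSpec]:
    """Candidate TransformSpecs for one family on this predictor's range."""
    if family in REVERSE_FAMILIES:
        xmax = float(np.max(x))
        return [TransformSpec(family, shift_constant=xmax + off) for off in k_offsets]
    if family is TransformFamily.EXPONENTIAL:
        rng = float(np.max(x) - np.min(x))
        if rng <= 0:
            return []
        return [TransformSpec(family, scale_constant=rng / 10.0)]
    return [TransformSpec(family)]


def _ols_fit(t: np.ndarray, y: np.ndarray):
    X = sm.add_constant(t)
    return sm.OLS(y, X).fit()


def fit_transformations(
    x: Sequence[float],
    y: Sequence[float],
    families: Sequence[TransformFamily] = FAMILY_ORDER,
    k_offsets: Sequence[float] = DEFAULT_K_OFFSETS,
) -> list[TransformFit]:
    """Bivariate OLS of y on each transformation of x, ranked by AICc.

    Inapplicable families (e.g. the logarithm of a non-positive predictor)
    are skipped with a logged warning.  For the reverse families the shift
    constant k is chosen over max(x) + offsets by AICc.  Ties are broken by
    the fixed family order, keeping the simplest description.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 10:
        raise ValueError("predictor and response must share length >= 10")
    fits: list[TransformFit] = []
    for family in families:
        best: Optional[TransformFit] = None
        for spec in _make_spec(TransformFamily(family), x, k_offsets):
            try:
                t = np.array([spec.apply(v) for v in x])
            except ValueError as err:
                log.warning("skipping %s transform: %s", family, err)
                break
            if not np.all(np.isfinite(t)):
                log.warning("skipping %s transform: non-finite values", family)
                break
            with np.errstate(divide="ignore"):
                res = _ols_fit(t, y)
                llf = float(res.llf)
            # an (effectively) perfect fit has no finite Gaussian ML likelihood;
            # score all such fits equally so ties resolve by the family order
            perfect = not math.isfinite(llf) or (
                res.ssr <= 1e-12 * max(1.0, float(np.var(y)) * x.size)
            )
            fit = TransformFit(
                spec=spec,
                aicc=float("-inf") if perfect else aicc(llf, K=3, n=x.size),
                log_likelihood=llf,
                slope=float(res.params[1]),
                intercept=float(res.params[0]),
            )
            if best is None or fit.aicc < best.aicc:
                best = fit
        if best is not None:
            fits.append(best)
    if not fits:
        raise ValueError("no applicable transformation family")
    order = {f: i for i, f in enumerate(FAMILY_ORDER)}
    fits.sort(key=lambda f: (round(f.aicc, 6), order[f.spec.family]))
    return fits


# ---------------------------------------------------------------------------
# adjustment model
# ---------------------------------------------------------------------------

def _predictor_value(rec: ParticipantRecord, predictor: Predictor) -> float:
    if predictor is Predictor.AGE:
        return float(rec.age)
    if predictor is Predictor.EDUCATION:
        return float(rec.education)
    return float(rec.sex.value)


def fit_adjustment_model(
    cohort: Sequence[ParticipantRecord],
    measure: Measure,
    selected: Mapping[Predictor, TransformSpec],
    responses: Mapping[str, float],
) -> AdjustmentModel:
    """Deviation-from-mean regression with reversed coefficients.

    The measure is regressed on the centered transformed predictors; the
    returned model stores the reversed-sign slopes and the sample means of
    the transformed predictors, so adding the adjustment removes the
    estimated demographic effect while preserving the cohort mean.
    """
    measure = Measure(measure)
    recs = [r for r in cohort if r.id in responses]
    if not recs:
        raise ValueError(f"no responses available for measure {measure.value}")
    y = np.array([responses[r.id] for r in recs])
    predictors = list(selected)
    cols, centers = [], []
    for pred in predictors:
        spec = selected[pred]
        t = np.array([spec.apply(_predictor_value(r, pred)) for r in recs])
        centers.append(float(t.mean()))
        cols.append(t - t.mean())
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: predictors are collinear")
    res = _ols_fit(X, y)
    terms = tuple(
        ModelTerm(
            predictor=pred,
            transform=selected[pred],
            coefficient=-float(res.params[i + 1]),
            centering_constant=centers[i],
        )
        for i, pred in enumerate(predictors)
    )
    return AdjustmentModel(measure=measure, terms=terms)


def build_correction_grid(
    model: AdjustmentModel,
    age_bands: Sequence[Band] = AGE_BANDS,
    education_bands: Sequence[Band] = EDUCATION_BANDS,
    sexes: Sequence[str] = ("F", "M"),
) -> dict:
    """Rounded banded adjustments, one per grid cell.

    Accuracy-style models (with education or sex terms) yield a grid keyed by
    (age_band, education_band, sex); an age-only model yields one keyed by
    age band.
    """
    from .scoring import demographic_adjustment  # local to avoid cycle at import

    used = set(model.predictors())
    age_axis = age_bands if Predictor.AGE in used else age_bands[:1]
    edu_axis = education_bands if Predictor.EDUCATION in used else (None,)
    sex_axis = sexes if Predictor.SEX in used else (None,)
    grid: dict = {}
    for ab in age_bands:
        for eb in edu_axis:
            for sx in sex_axis:
                value = demographic_adjustment(
                    model,
                    age=ab.representative,
                    education=eb.representative if eb else education_bands[0].representative,
                    sex=0 if sx in (None, "F") else 1,
                    mode="exact",
                )
                if eb is None and sx is None:
                    grid[ab.label] = value
                else:
                    grid[(ab.label, eb.label if eb else "", sx or "")] = value
    return grid


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """Multiple-regression power computation via the noncentral F distribution."""

    n_predictors: int = 3
    effect_size_f2: float = 0.04
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.n_predictors < 1:
            raise ValueError("need at least one predictor")
        for name in ("effect_size_f2", "alpha", "power"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


def regression_power(n: int, spec: PowerSpec) -> float:
    """Power of the overall F test at total sample size n (noncentrality f2*n)."""
    u = spec.n_predictors
    v = n - u - 1
    if v < 1:
        return 0.0
    fcrit = stats.f.isf(spec.alpha, u, v)
    return float(stats.ncf.sf(fcrit, u, v, spec.effect_size_f2 * n))


def power_min_n(spec: PowerSpec = PowerSpec(), n_max: int = 10_000_000) -> int:
    """Smallest total N reaching the target power."""
    lo, hi = spec.n_predictors + 2, spec.n_predictors + 2
    while regression_power(hi, spec) < spec.power:
        hi *= 2
        if hi > n_max:
            raise ValueError("target power unreachable within n_max")
    while lo < hi:
        mid = (lo + hi) // 2
        if regression_power(mid, spec) >= spec.power:
            hi = mid
        else:
            lo = mid + 1
    return lo


# ---------------------------------------------------------------------------
# end-to-end derivation
# ---------------------------------------------------------------------------

MODEL_SUBSETS: Tuple[Tuple[Predictor, ...], ...] = tuple(
    subset
    for size in (1, 2, 3)
    for subset in itertools.combinations(
        (Predictor.AGE, Predictor.EDUCATION, Predictor.SEX), size
    )
)


def subset_label(subset: Sequence[Predictor]) -> str:
    names = {Predictor.AGE: "Age", Predictor.EDUCATION: "Edu", Predictor.SEX: "Sex"}
    return " + ".join(names[p] for p in subset)


@dataclass
class DerivationConfig:
    """Rule constants, search space and band definitions of the pipeline."""

    outlier_rule: OutlierRule = field(default_factory=OutlierRule)
    families: Tuple[TransformFamily, ...] = FAMILY_ORDER
    k_offsets: Tuple[float, ...] = DEFAULT_K_OFFSETS
    age_bands: Tuple[Band, ...] = AGE_BANDS
    education_bands: Tuple[Band, ...] = EDUCATION_BANDS
    tolerance: scales_mod.ToleranceSpec = field(default_factory=scales_mod.ToleranceSpec)
    es_bands: scales_mod.ESBandSpec = field(default_factory=scales_mod.ESBandSpec)
    percentile_levels: Tuple[float, ...] = scales_mod.DEFAULT_PERCENTILE_LEVELS
    #: optional {measure: {predictor: TransformSpec}} bypassing the searches,
    #: e.g. for parameter-recovery experiments against a known generating model
    fixed_terms: Optional[Mapping[Measure, Mapping[Predictor, TransformSpec]]] = None


@dataclass
class MeasureDerivation:
    """Per-measure diagnostics of one derivation run."""

    transform_search: dict[Predictor, list[TransformFit]]
    selected_transforms: dict[Predictor, TransformSpec]
    model_comparison: list[ModelComparisonRow]
    selected_subset: Tuple[Predictor, ...]
    model: AdjustmentModel
    grid: dict
    scales: NormScales


@dataclass
class DerivationResult:
    threshold_s: float
    removed_ids: list[str]
    n_after_filter: int
    line_corrections: LineCorrectionTable
    accuracy: MeasureDerivation
    time: MeasureDerivation


def _derive_measure(
    cohort: Sequence[ParticipantRecord],
    measure: Measure,
    responses: Mapping[str, float],
    direction: Direction,
    config: DerivationConfig,
) -> MeasureDerivation:
    recs = [r for r in cohort if r.id in responses]
    y = np.array([responses[r.id] for r in recs])
    fixed = (config.fixed_terms or {}).get(measure)
    search: dict[Predictor, list[TransformFit]] = {}
    selected: dict[Predictor, TransformSpec] = {}
    for pred in (Predictor.AGE, Predictor.EDUCATION, Predictor.SEX):
        if fixed is not None:
            if pred in fixed:
                selected[pred] = fixed[pred]
            continue
        x = np.array([_predictor_value(r, pred) for r in recs])
        fits = fit_transformations(x, y, config.families, config.k_offsets)
        search[pred] = fits
        selected[pred] = fits[0].spec

    if fixed is not None:
        subset = tuple(selected)
        comparison: list[ModelComparisonRow] = []
    else:
        candidates = []
        for subset_ in MODEL_SUBSETS:
            cols = []
            for pred in subset_:
                spec = selected[pred]
                cols.append(np.array([spec.apply(_predictor_value(r, pred)) for r in recs]))
            res = _ols_fit(np.column_stack(cols), y)
            candidates.append(
                FittedCandidate(
                    label=subset_label(subset_),
                    log_likelihood=float(res.llf),
                    K=len(subset_) + 2,
                    n=len(recs),
                )
            )
        comparison = compare_models(candidates)
        label_to_subset = {subset_label(s): s for s in MODEL_SUBSETS}
        subset = label_to_subset[comparison[0].model_label]

    model = fit_adjustment_model(
        cohort, measure, {p: selected[p] for p in subset}, responses
    )
    grid = build_correction_grid(model, config.age_bands, config.education_bands)

    corrected = np.array(
        [
            responses[r.id]
            + model.evaluate(
                {
                    Predictor.AGE: float(r.age),
                    Predictor.EDUCATION: float(r.education),
                    Predictor.SEX: float(r.sex.value),
                }
            )
            for r in recs
        ]
    )
    side = (
        scales_mod.ToleranceSide.LOWER_TAIL_IS_IMPAIRED
        if direction is Direction.HIGHER_BETTER
        else scales_mod.ToleranceSide.UPPER_TAIL_IS_IMPAIRED
    )
    spec = replace(config.tolerance, side=side)
    outer, inner = scales_mod.tolerance_limits(corrected, spec)
    outer, inner = round(outer, 4), round(inner, 4)
    percentiles = scales_mod.percentile_table(
        corrected, config.percentile_levels, direction
    )
    cuts = scales_mod.es_cut_values(corrected, outer, config.es_bands, direction)
    norm_scales = NormScales(
        measure=measure,
        direction=direction,
        tolerance_outer=round(outer, 1),
        tolerance_inner=round(inner, 1),
        percentiles=percentiles,
        es_cuts=cuts,
        grid=grid,
    )
    return MeasureDerivation(
        transform_search=search,
        selected_transforms=selected,
        model_comparison=comparison,
        selected_subset=subset,
        model=model,
        grid=grid,
        scales=norm_scales,
    )


def derive_norms(
    cohort: Sequence[ParticipantRecord],
    config: DerivationConfig = DerivationConfig(),
) -> DerivationResult:
    """Run the full pipeline: filter, uniformize, select, fit, tabulate."""
    threshold = outlier_threshold(cohort, config.outlier_rule)
    kept = filter_outlier_cases(cohort, threshold)
    removed = sorted(set(r.id for r in cohort) - set(r.id for r in kept))
    n = len(kept)
    min_n = scales_mod.minimum_n(config.tolerance)
    if n < min_n:
        raise ValueError(
            f"{n} participants after filtering; distribution-free "
            f"{config.tolerance.coverage:.0%}/{config.tolerance.confidence:.0%} "
            f"tolerance limits need at least {min_n}"
        )
    table = line_correction_factors(kept)
    acc_responses = {r.id: float(sum(o.correct for o in r.outcomes.values())) for r in kept}
    time_responses = mean_corrected_times_unrounded(kept, table)
    accuracy = _derive_measure(
        kept, Measure.ACCURACY, acc_responses, Direction.HIGHER_BETTER, config
    )
    time = _derive_measure(
        kept, Measure.TIME, time_responses, Direction.LOWER_BETTER, config
    )
    return DerivationResult(
        threshold_s=threshold,
        removed_ids=removed,
        n_after_filter=n,
        line_corrections=table,
        accuracy=accuracy,
        time=time,
    )
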