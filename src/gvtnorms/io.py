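"""File formats: scoresheet CSV, norms JSON document, scored output.

The scoresheet is one row per participant: ``id, age, education_years, sex``
followed, for each of the ten lines (A_A..A_E, B_A..B_E), by ``<line>_ok``
(0/1) and ``<line>_time`` (seconds, blank when the line was not followed
correctly).  The norms document is a JSON file holding the line corrections,
the adjustment models, the correction grids and the clinical scales; it is
validated structurally on load and round-trips byte-identically.  All writes
go through a temp-file + rename so a crashed run never leaves a truncated
file behind.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .types import (
    LINE_IDS,
    AdjustmentModel,
    Direction,
    LineCorrectionTable,
    LineId,
    LineOutcome,
    Measure,
    ModelTerm,
    NormScales,
    ParticipantRecord,
    Predictor,
    ScoredResult,
    Sex,
    TransformSpec,
)

PathLike = Union[str, Path]


class NormsValidationError(ValueError):
    """A norms document fails its structural contract."""


# ---------------------------------------------------------------------------
# scoresheet CSV
# ---------------------------------------------------------------------------

SCORESHEET_COLUMNS = ["id", "age", "education_years", "sex"] + [
    col for lid in LINE_IDS for col in (f"{lid}_ok", f"{lid}_time")
]


def read_scoresheet(path: PathLike) -> list[ParticipantRecord]:
    """Parse a scoresheet CSV into participant records."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in SCORESHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scoresheet missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        outcomes: dict[LineId, LineOutcome] = {}
        for lid in LINE_IDS:
            ok = int(row[f"{lid}_ok"])
            if ok:
                outcomes[lid] = LineOutcome(True, float(row[f"{lid}_time"]))
            else:
                outcomes[lid] = LineOutcome(False)
        try:
            records.append(
                ParticipantRecord(
                    id=str(row["id"]),
                    age=int(row["age"]),
                    education=int(row["education_years"]),
                    sex=Sex.parse(row["sex"]),
                    outcomes=outcomes,
                )
            )
        except (ValueError, TypeError) as err:
            raise ValueError(f"scoresheet row {i} (id={row['id']!r}): {err}") from err
    return records


def write_scoresheet(cohort: Sequence[ParticipantRecord], path: PathLike) -> None:
    rows = []
    for rec in cohort:
        row: dict = {
            "id": rec.id,
            "age": rec.age,
            "education_years": rec.education,
            "sex": rec.sex.name,
        }
        for lid in LINE_IDS:
            out = rec.outcomes[lid]
            row[f"{lid}_ok"] = int(out.correct)
            row[f"{lid}_time"] = round(out.time_s, 3) if out.correct else None
        rows.append(row)
    df = pd.DataFrame(rows, columns=SCORESHEET_COLUMNS)
    _atomic_write(path, df.to_csv(index=False))


# ---------------------------------------------------------------------------
# norms document
# ---------------------------------------------------------------------------

@dataclass
class NormsDocument:
    """A complete norm set: corrections, models, grids and scales."""

    line_corrections: LineCorrectionTable
    models: dict[Measure, AdjustmentModel]
    scales: dict[Measure, NormScales]
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "format": "gvt-norms/1",
            "metadata": dict(self.metadata),
            "line_corrections": {
                str(lid): self.line_corrections.correction_s[lid] for lid in LINE_IDS
            },
            "models": {
                m.value: _model_to_dict(self.models[m]) for m in sorted(self.models)
            },
            "scales": {
                m.value: _scales_to_dict(self.scales[m]) for m in sorted(self.scales)
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "NormsDocument":
        validate_norms_dict(doc)
        corrections = LineCorrectionTable(
            {LineId.parse(k): float(v) for k, v in doc["line_corrections"].items()}
        )
        models = {
            Measure(name): _model_from_dict(name, d)
            for name, d in doc["models"].items()
        }
        scales = {
            Measure(name): _scales_from_dict(name, d)
            for name, d in doc["scales"].items()
        }
        return cls(
            line_corrections=corrections,
            models=models,
            scales=scales,
            metadata=dict(doc.get("metadata", {})),
        )


def _model_to_dict(model: AdjustmentModel) -> dict:
    return {
        "measure": model.measure.value,
        "terms": [
            {
                "predictor": t.predictor.value,
                "transform": _transform_to_dict(t.transform),
                "coefficient": t.coefficient,
                "centering_constant": t.centering_constant,
            }
            for t in model.terms
        ],
    }


def _transform_to_dict(spec: TransformSpec) -> dict:
    d: dict = {"family": spec.family.value}
    if spec.shift_constant is not None:
        d["shift_constant"] = spec.shift_constant
    if spec.scale_constant is not None:
        d["scale_constant"] = spec.scale_constant
    return d


def _model_from_dict(name: str, d: dict) -> AdjustmentModel:
    terms = tuple(
        ModelTerm(
            predictor=Predictor(t["predictor"]),
            transform=TransformSpec(
                family=t["transform"]["family"],
                shift_constant=t["transform"].get("shift_constant"),
                scale_constant=t["transform"].get("scale_constant"),
            ),
            coefficient=float(t["coefficient"]),
            centering_constant=float(t["centering_constant"]),
        )
        for t in d["terms"]
    )
    return AdjustmentModel(measure=Measure(name), terms=terms)


def _grid_to_dict(grid: Mapping) -> dict:
    out = {}
    for key, value in grid.items():
        out["|".join(key) if isinstance(key, tuple) else str(key)] = value
    return out


def _grid_from_dict(d: Mapping) -> dict:
    out = {}
    for key, value in d.items():
        parts = key.split("|")
        out[tuple(parts) if len(parts) > 1 else key] = float(value)
    return out


def _scales_to_dict(s: NormScales) -> dict:
    return {
        "direction": s.direction.value,
        "tolerance": {"outer": s.tolerance_outer, "inner": s.tolerance_inner},
        "percentiles": {str(_int_if_whole(k)): v for k, v in sorted(s.percentiles.items())},
        "es_cuts": list(s.es_cuts),
        "grid": _grid_to_dict(s.grid),
    }


def _int_if_whole(x: float):
    return int(x) if float(x).is_integer() else x


def _scales_from_dict(name: str, d: dict) -> NormScales:
    return NormScales(
        measure=Measure(name),
        direction=Direction(d["direction"]),
        tolerance_outer=float(d["tolerance"]["outer"]),
        tolerance_inner=float(d["tolerance"]["inner"]),
        percentiles={float(k): float(v) for k, v in d["percentiles"].items()},
        es_cuts=tuple(float(v) for v in d["es_cuts"]),
        grid=_grid_from_dict(d.get("grid", {})),
    )


_REQUIRED_TOP = ("line_corrections", "models", "scales")


def validate_norms_dict(doc: dict) -> None:
    """Structural validation; raises :class:`NormsValidationError`."""
    if not isinstance(doc, dict):
        raise NormsValidationError("norms document must be a JSON object")
    for key in _REQUIRED_TOP:
        if key not in doc:
            raise NormsValidationError(f"norms document missing field {key!r}")
    lc = doc["line_corrections"]
    expected = {str(lid) for lid in LINE_IDS}
    if set(lc) != expected:
        raise NormsValidationError(
            f"line_corrections must cover exactly the line ids {sorted(expected)}"
        )
    for name in ("accuracy", "time"):
        if name not in doc["models"]:
            raise NormsValidationError(f"models must include {name!r}")
        if name not in doc["scales"]:
            raise NormsValidationError(f"scales must include {name!r}")
    for name, model in doc["models"].items():
        if not model.get("terms"):
            raise NormsValidationError(f"model {name!r} has no terms")
        for t in model["terms"]:
            for key in ("predictor", "transform", "coefficient", "centering_constant"):
                if key not in t:
                    raise NormsValidationError(f"model {name!r} term missing {key!r}")
    for name, s in doc["scales"].items():
        for key in ("direction", "tolerance", "percentiles", "es_cuts"):
            if key not in s:
                raise NormsValidationError(f"scales {name!r} missing {key!r}")
        if len(s["es_cuts"]) != 4:
            raise NormsValidationError(f"scales {name!r} es_cuts must have 4 boundaries")
        if not s["percentiles"]:
            raise NormsValidationError(f"scales {name!r} has an empty percentile table")
        direction = Direction(s["direction"])
        levels = sorted(float(k) for k in s["percentiles"])
        values = [float(s["percentiles"][str(_int_if_whole(l))]) for l in levels]
        diffs = [b - a for a, b in zip(values, values[1:])]
        if direction is Direction.HIGHER_BETTER and any(d < 0 for d in diffs):
            raise NormsValidationError(f"{name!r} percentile values must be nondecreasing")
        if direction is Direction.LOWER_BETTER and any(d > 0 for d in diffs):
            raise NormsValidationError(f"{name!r} percentile values must be nonincreasing")


def dumps_norms(doc: NormsDocument) -> str:
    return json.dumps(doc.to_dict(), indent=2, sort_keys=True) + "\n"


def save_norms(doc: NormsDocument, path: PathLike) -> None:
    _atomic_write(path, dumps_norms(doc))


def load_norms(path: PathLike) -> NormsDocument:
    with open(path, "r", encoding="utf-8") as fh:
        return NormsDocument.from_dict(json.load(fh))


def published_norms() -> NormsDocument:
    """The packaged published norm set (adult norms, ages 20-79, n = 526)."""
    from importlib.resources import files

    text = files("gvtnorms").joinpath("data/published_norms.json").read_text("utf-8")
    return NormsDocument.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# scored output
# ---------------------------------------------------------------------------

def scored_to_row(result: ScoredResult) -> dict:
    row: dict = {
        "id": result.id,
        "raw_accuracy": result.raw_accuracy,
        "demographic_correction_accuracy": result.demographic_correction_accuracy,
        "corrected_accuracy": result.corrected_accuracy,
        "percentile_accuracy": str(result.percentile_accuracy),
        "es_accuracy": result.es_accuracy,
        "classification_accuracy": result.classification_accuracy.value,
        "mean_corrected_time": result.mean_corrected_time,
        "demographic_correction_time": result.demographic_correction_time,
        "corrected_time": result.corrected_time,
        "percentile_time": (
            str(result.percentile_time) if result.percentile_time else "NA"
        ),
        "es_time": result.es_time if result.es_time is not None else "NA",
        "classification_time": (
            result.classification_time.value if result.classification_time else "NA"
        ),
        "extrapolated": int(result.extrapolated),
    }
    return row


SCORED_COLUMNS = [
    "id", "raw_accuracy", "demographic_correction_accuracy", "corrected_accuracy",
    "percentile_accuracy", "es_accuracy", "classification_accuracy",
    "mean_corrected_time", "demographic_correction_time", "corrected_time",
    "percentile_time", "es_time", "classification_time", "extrapolated",
]


def write_scored(
    results: Sequence[ScoredResult], path: PathLike, fmt: Optional[str] = None
) -> None:
    """Write scored results as CSV (default) or JSON (by extension or ``fmt``)."""
    fmt = fmt or ("json" if str(path).endswith(".json") else "csv")
    rows = [scored_to_row(r) for r in results]
    if fmt == "json":
        _atomic_write(path, json.dumps(rows, indent=2) + "\n")
    else:
        df = pd.DataFrame(rows, columns=SCORED_COLUMNS)
        _atomic_write(path, df.to_csv(index=False))


def document_from_derivation(result, metadata: Optional[dict] = None) -> NormsDocument:
    """Assemble a NormsDocument from a derivation result (duck-typed)."""
    return NormsDocument(
        line_corrections=result.line_corrections.rounded(1),
        models={
            Measure.ACCURACY: result.accuracy.model,
            Measure.TIME: result.time.model,
        },
        scales={
            Measure.ACCURACY: result.accuracy.scales,
            Measure.TIME: result.time.scales,
        },
        metadata=metadata or {},
    )


def _atomic_write(path: PathLike, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
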