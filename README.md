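# gvtnorms

Normative scoring and norm derivation for the **Groffman Visual Tracing
(GVT) test**, a paper-based oculomotor task used in optometric and
neuropsychological assessment. The examinee follows each of five intertwined
lines on two cards (A and B) with the eyes only, from a letter at the top to
a number at the bottom; each of the 10 lines is scored correct/incorrect and
timed (the time is recorded only when the line was followed correctly).

The package is for clinicians who need to turn a raw GVT scoresheet into
demographically adjusted scores, percentiles, equivalent scores (ES) and an
impaired / uncertain / normal-range classification using the published adult
norms (ages 20–79, n = 526), and for researchers who want to re-derive a
complete norm set from a new cohort — or from a synthetic one with known
ground truth.

## The scoring model

Two measures are scored per examinee:

* **Accuracy** `A` ∈ {0..10}: number of lines followed correctly.
* **Mean execution time** `T`: each valid line's time first receives an
  additive per-line constant (the *first correction*, making all 10 lines
  share the same cohort mean time), then the corrected times are averaged.

Raw scores are demographically adjusted by regression-based corrections with
reversed coefficients, so that adding the correction removes the estimated
effect of age, education and sex:

```
AC = 0.000597 (Age² − 2365.458) + 16.77 (1/Edu − 0.0818) − 0.455 (Sex − 0.445)
TC = 4.364 (ln(86.9 − Age) − 3.7)
```

with sex coded F = 0, M = 1 and `ln` the natural logarithm. The corrected
scores `A + AC` and `T + TC` are referred to non-parametric one-sided 95%
tolerance limits (95% confidence) for the impaired tail, a percentile table,
and rank-based equivalent scores ES0–ES4 (ES0 = beyond the outer tolerance
limit, ES4 = better than the median).

The norm-derivation pipeline reruns the whole construction on any cohort:
case-wise deletion of extreme outliers (any execution time ≥ Q3 + 3·IQR of
the pooled times), line uniformization, an AICc search over nine predictor
transformations, AICc model selection with Akaike weights over the seven
predictor subsets, the deviation-from-mean adjustment regression, correction
grids, tolerance limits and scales. See `docs/methods.md` for the details
and the modelling choices.

## Worked example

Score the published low-accuracy case — a 23-year-old man with 13 years of
education who followed 3 of 10 lines correctly (card A line A in 12.8 s,
card B lines A and D in 12.7 s and 14.4 s):

```python
import gvtnorms as g
from gvtnorms.types import LineId, LineOutcome, ParticipantRecord, Sex, LINE_IDS

times = {LineId("A", "A"): 12.8, LineId("B", "A"): 12.7, LineId("B", "D"): 14.4}
record = ParticipantRecord(
    id="case", age=23, education=13, sex=Sex.M,
    outcomes={lid: LineOutcome(True, times[lid]) if lid in times
              else LineOutcome(False) for lid in LINE_IDS},
)
norms = g.published_norms()
r = g.score_record(record, norms.line_corrections, norms.models, norms.scales)
print(r.raw_accuracy, r.demographic_correction_accuracy, r.corrected_accuracy,
      str(r.percentile_accuracy), r.es_accuracy, r.classification_accuracy.value)
print(r.mean_corrected_time, r.demographic_correction_time, r.corrected_time,
      str(r.percentile_time), r.es_time)
```

prints

```
3 -1.2 1.8 4 1 uncertain
15.8 1.9 17.7 70-75 4
```

read as: accuracy 3 is adjusted by −1.2 to 1.8, the 4th percentile, ES 1,
inside the uncertainty band between the tolerance limits (a borderline
result); mean corrected time 15.8 s is adjusted by +1.9 to 17.7 s, between
the 70th and 75th percentile, ES 4 — an examinee who trades accuracy for
speed.

The same flows exist as a CLI:

```
gvt simulate --seed 1 --n 526 --out cohort.csv     # synthetic cohort
gvt derive cohort.csv --out norms.json             # derive a norm set
gvt score cohort.csv --norms norms.json --out scored.csv
```

`gvt score` without `--norms` uses the packaged published norms.

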