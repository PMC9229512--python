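"""Published norm tables used as test oracles (values typed from the source)."""

from gvtnorms.types import LINE_IDS, LineId

#: Per-line mean execution times (s) of the normative cohort, canonical order.
TABLE3_LINE_MEANS = dict(
    zip(LINE_IDS, (18.3, 22.9, 28.7, 22.9, 19.4, 16.4, 20.7, 21.3, 23.6, 25.7))
)

#: Per-line valid counts out of 526.
TABLE3_VALID_COUNTS = dict(
    zip(LINE_IDS, (354, 317, 268, 255, 392, 369, 336, 386, 302, 231))
)

#: Published line-uniformization corrections (s).
TABLE8_CORRECTIONS = dict(
    zip(LINE_IDS, (3.6, -0.9, -6.7, -0.9, 2.6, 5.7, 1.3, 0.7, -1.7, -3.7))
)

#: Accuracy correction grid: (age_band, education_band, sex) -> correction.
TABLE5_ACCURACY_GRID = {}
_ROWS_F = {
    "20-29": (4.5, 0.2, -0.7, -1.2), "30-39": (4.8, 0.5, -0.3, -0.8),
    "40-49": (5.3, 1.0, 0.1, -0.4), "50-59": (5.9, 1.6, 0.7, 0.2),
    "60-69": (6.6, 2.3, 1.4, 0.9), "70-79": (7.4, 3.1, 2.3, 1.8),
}
_ROWS_M = {
    "20-29": (4.0, -0.3, -1.2, -1.6), "30-39": (4.4, 0.1, -0.8, -1.3),
    "40-49": (4.9, 0.5, -0.3, -0.8), "50-59": (5.4, 1.1, 0.3, -0.2),
    "60-69": (6.2, 1.8, 1.0, 0.5), "70-79": (7.0, 2.7, 1.8, 1.3),
}
_EDU = ("0-5", "6-8", "9-13", ">13")
for _sex, _rows in (("F", _ROWS_F), ("M", _ROWS_M)):
    for _age, _vals in _rows.items():
        for _band, _v in zip(_EDU, _vals):
            TABLE5_ACCURACY_GRID[(_age, _band, _sex)] = _v

#: Execution-time correction grid by age band.
TABLE10_TIME_GRID = {
    "20-29": 1.9, "30-39": 1.1, "40-49": 0.2,
    "50-59": -1.0, "60-69": -2.6, "70-79": -5.2,
}

#: Model-comparison tables: (label, K, printed LL, printed AICc), n = 526.
TABLE4_ACCURACY_MODELS = [
    ("Age + Edu + Sex", 5, -1209.8, 2429.72),
    ("Age + Edu", 4, -1212.09, 2432.25),
    ("Age + Sex", 4, -1217.64, 2443.36),
    ("Age", 3, -1219.47, 2444.99),
    ("Edu + Sex", 4, -1238.61, 2485.29),
    ("Edu", 3, -1240.32, 2486.68),
    ("Sex", 3, -1267.52, 2541.07),
]
TABLE9_TIME_MODELS = [
    ("Age", 3, -1722.64, 3451.33),
    ("Age + Sex", 4, -1722.12, 3452.32),
    ("Age + Edu", 4, -1722.41, 3452.90),
    ("Age + Edu + Sex", 5, -1721.85, 3453.82),
    ("Edu", 3, -1736.81, 3479.66),
    ("Edu + Sex", 4, -1736.42, 3480.92),
    ("Sex", 3, -1742.19, 3490.42),
]

#: Worked example 1: 48-year-old woman, university education, all lines correct.
EX1_RAW_TIMES = dict(
    zip(LINE_IDS, (19.4, 21.0, 33.9, 23.9, 18.4, 16.5, 13.3, 19.7, 20.3, 19.7))
)
#: The example's printed first-correction row (card B line E appears as +3.7
#: there, where the published correction table prints -3.7).
EX1_PRINTED_CORRECTIONS = dict(
    zip(LINE_IDS, (3.6, -0.9, -6.7, -0.9, 2.6, 5.7, 1.3, 0.7, -1.7, 3.7))
)
EX1_ADJUSTED_TIMES = dict(
    zip(LINE_IDS, (23.0, 20.1, 27.2, 23.0, 21.0, 22.2, 14.6, 20.4, 18.6, 23.4))
)

#: Worked example 2: 23-year-old man, 13 years of education, 3 lines correct.
EX2_RAW_TIMES = {
    LineId("A", "A"): 12.8,
    LineId("B", "A"): 12.7,
    LineId("B", "D"): 14.4,
}
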