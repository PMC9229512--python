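{
  "format": "gvt-norms/1",
  "metadata": {
    "name": "GVT adult norms",
    "cohort_n": 526,
    "age_range": [20, 79],
    "source": "published normative study of the adult Groffman Visual Tracing test",
    "version": "1.0"
  },
  "line_corrections": {
    "A_A": 3.6, "A_B": -0.9, "A_C": -6.7, "A_D": -0.9, "A_E": 2.6,
    "B_A": 5.7, "B_B": 1.3, "B_C": 0.7, "B_D": -1.7, "B_E": -3.7
  },
  "models": {
    "accuracy": {
      "measure": "accuracy",
      "terms": [
        {
          "predictor": "age",
          "transform": {"family": "quadratic"},
          "coefficient": 0.000597,
          "centering_constant": 2365.458
        },
        {
          "predictor": "education",
          "transform": {"family": "inverse"},
          "coefficient": 16.77,
          "centering_constant": 0.0818
        },
        {
          "predictor": "sex",
          "transform": {"family": "linear"},
          "coefficient": -0.455,
          "centering_constant": 0.445
        }
      ]
    },
    "time": {
      "measure": "time",
      "terms": [
        {
          "predictor": "age",
          "transform": {"family": "logarithmic_reverse", "shift_constant": 86.9},
          "coefficient": 4.364,
          "centering_constant": 3.7
        }
      ]
    }
  },
  "scales": {
    "accuracy": {
      "direction": "higher_better",
      "tolerance": {"outer": 1.6, "inner": 2.1},
      "percentiles": {
        "1": 0.7, "2": 1.0, "3": 1.6, "4": 1.8, "5": 2.0,
        "10": 2.7, "15": 3.4, "20": 3.9, "25": 4.4, "30": 4.8,
        "35": 5.2, "40": 5.5, "45": 5.9, "50": 6.3, "55": 6.6,
        "60": 6.9, "65": 7.3, "70": 7.6, "75": 8.0, "80": 8.3,
        "85": 8.7, "90": 9.1, "95": 9.7, "99": 10.9
      },
      "es_cuts": [1.6, 3.7, 5.1, 6.3],
      "grid": {
        "20-29|0-5|F": 4.5, "20-29|6-8|F": 0.2, "20-29|9-13|F": -0.7, "20-29|>13|F": -1.2,
        "30-39|0-5|F": 4.8, "30-39|6-8|F": 0.5, "30-39|9-13|F": -0.3, "30-39|>13|F": -0.8,
        "40-49|0-5|F": 5.3, "40-49|6-8|F": 1.0, "40-49|9-13|F": 0.1, "40-49|>13|F": -0.4,
        "50-59|0-5|F": 5.9, "50-59|6-8|F": 1.6, "50-59|9-13|F": 0.7, "50-59|>13|F": 0.2,
        "60-69|0-5|F": 6.6, "60-69|6-8|F": 2.3, "60-69|9-13|F": 1.4, "60-69|>13|F": 0.9,
        "70-79|0-5|F": 7.4, "70-79|6-8|F": 3.1, "70-79|9-13|F": 2.3, "70-79|>13|F": 1.8,
        "20-29|0-5|M": 4.0, "20-29|6-8|M": -0.3, "20-29|9-13|M": -1.2, "20-29|>13|M": -1.6,
        "30-39|0-5|M": 4.4, "30-39|6-8|M": 0.1, "30-39|9-13|M": -0.8, "30-39|>13|M": -1.3,
        "40-49|0-5|M": 4.9, "40-49|6-8|M": 0.5, "40-49|9-13|M": -0.3, "40-49|>13|M": -0.8,
        "50-59|0-5|M": 5.4, "50-59|6-8|M": 1.1, "50-59|9-13|M": 0.3, "50-59|>13|M": -0.2,
        "60-69|0-5|M": 6.2, "60-69|6-8|M": 1.8, "60-69|9-13|M": 1.0, "60-69|>13|M": 0.5,
        "70-79|0-5|M": 7.0, "70-79|6-8|M": 2.7, "70-79|9-13|M": 1.8, "70-79|>13|M": 1.3
      }
    },
    "time": {
      "direction": "lower_better",
      "tolerance": {"outer": 37.4, "inner": 34.0},
      "percentiles": {
        "1": 42.8, "2": 40.4, "3": 37.7, "4": 36.5, "5": 35.0,
        "10": 32.0, "15": 29.7, "20": 27.8, "25": 26.1, "30": 25.0,
        "35": 23.8, "40": 22.8, "45": 21.5, "50": 20.7, "55": 20.1,
        "60": 19.2, "65": 18.5, "70": 17.8, "75": 17.2, "80": 16.6,
        "85": 15.8, "90": 14.7, "95": 13.4, "99": 10.3
      },
      "es_cuts": [37.4, 28.8, 23.8, 20.7],
      "grid": {
        "20-29": 1.9, "30-39": 1.1, "40-49": 0.2,
        "50-59": -1.0, "60-69": -2.6, "70-79": -5.2
      }
    }
  }
}
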