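{
  "version": "legall-1993-v1",
  "description": "SAPS-II point assignments (Le Gall, Lemeshow & Saulnier 1993). Continuous components are half-open bins [lo, hi); null bounds are unbounded. pao2_fio2_ratio applies only to ventilated/CPAP patients; a null ratio encodes 'not ventilated' and scores 0.",
  "continuous": {
    "age": [
      {"lo": null, "hi": 40, "points": 0},
      {"lo": 40, "hi": 60, "points": 7},
      {"lo": 60, "hi": 70, "points": 12},
      {"lo": 70, "hi": 75, "points": 15},
      {"lo": 75, "hi": 80, "points": 16},
      {"lo": 80, "hi": null, "points": 18}
    ],
    "heart_rate": [
      {"lo": null, "hi": 40, "points": 11},
      {"lo": 40, "hi": 70, "points": 2},
      {"lo": 70, "hi": 120, "points": 0},
      {"lo": 120, "hi": 160, "points": 4},
      {"lo": 160, "hi": null, "points": 7}
    ],
    "systolic_bp": [
      {"lo": null, "hi": 70, "points": 13},
      {"lo": 70, "hi": 100, "points": 5},
      {"lo": 100, "hi": 200, "points": 0},
      {"lo": 200, "hi": null, "points": 2}
    ],
    "temperature": [
      {"lo": null, "hi": 39, "points": 0},
      {"lo": 39, "hi": null, "points": 3}
    ],
    "pao2_fio2_ratio": [
      {"lo": null, "hi": 100, "points": 11},
      {"lo": 100, "hi": 200, "points": 9},
      {"lo": 200, "hi": null, "points": 6}
    ],
    "urine_output": [
      {"lo": null, "hi": 500, "points": 11},
      {"lo": 500, "hi": 1000, "points": 4},
      {"lo": 1000, "hi": null, "points": 0}
    ],
    "bun": [
      {"lo": null, "hi": 28, "points": 0},
      {"lo": 28, "hi": 84, "points": 6},
      {"lo": 84, "hi": null, "points": 10}
    ],
    "sodium": [
      {"lo": null, "hi": 125, "points": 5},
      {"lo": 125, "hi": 145, "points": 0},
      {"lo": 145, "hi": null, "points": 1}
    ],
    "potassium": [
      {"lo": null, "hi": 3, "points": 3},
      {"lo": 3, "hi": 5, "points": 0},
      {"lo": 5, "hi": null, "points": 3}
    ],
    "bicarbonate": [
      {"lo": null, "hi": 15, "points": 6},
      {"lo": 15, "hi": 20, "points": 3},
      {"lo": 20, "hi": null, "points": 0}
    ],
    "bilirubin": [
      {"lo": null, "hi": 4, "points": 0},
      {"lo": 4, "hi": 6, "points": 4},
      {"lo": 6, "hi": null, "points": 9}
    ],
    "wbc": [
      {"lo": null, "hi": 1, "points": 12},
      {"lo": 1, "hi": 20, "points": 0},
      {"lo": 20, "hi": null, "points": 3}
    ],
    "gcs": [
      {"lo": null, "hi": 6, "points": 26},
      {"lo": 6, "hi": 9, "points": 13},
      {"lo": 9, "hi": 11, "points": 7},
      {"lo": 11, "hi": 14, "points": 5},
      {"lo": 14, "hi": 16, "points": 0}
    ]
  },
  "categorical": {
    "chronic_disease": {
      "none": 0,
      "metastatic_cancer": 9,
      "hematologic_malignancy": 10,
      "aids": 17
    },
    "admission_type": {
      "scheduled_surgical": 0,
      "medical": 6,
      "unscheduled_surgical": 8
    }
  }
}
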