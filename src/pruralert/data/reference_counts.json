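{
  "description": "Published summary counts from the retrospective cohort of collar-monitored dogs (two consecutive 292-day periods; alerts visible to owners only in period 2). 2x2 cells are [a, b, c, d]: a/b = period-2 alerts associated/not associated with a 4-week clinic visit, c/d = same for period 1.",
  "periods": {
    "1": {
      "n_dogs": 7191,
      "total_alerts": 113530,
      "alert_visits": 5382,
      "total_visits": 15278,
      "total_medications": 10829,
      "medications_within_window": 4201,
      "median_alerts_per_dog": 9.0,
      "alert_range_per_dog": 60,
      "max_alerts_per_dog": 61
    },
    "2": {
      "n_dogs": 6684,
      "total_alerts": 93217,
      "alert_visits": 6980,
      "total_visits": 12900,
      "total_medications": 9863,
      "medications_within_window": 5457,
      "median_alerts_per_dog": 11.0,
      "alert_range_per_dog": 45,
      "max_alerts_per_dog": 46
    }
  },
  "subgroup_sizes": {
    "1": {"0": 2845, "1": 2495, "2": 1684, "3": 167},
    "2": {"0": 3062, "1": 2025, "2": 1440, "3": 157}
  },
  "two_by_two": {
    "scratch": {
      "infrequent": [2293, 26414, 673, 17666],
      "occasional": [2281, 33995, 2559, 54360],
      "elevated": [1543, 18812, 1819, 31038],
      "severe": [863, 7016, 331, 5084]
    },
    "lick": {
      "infrequent": [665, 10476, 178, 5944],
      "occasional": [2790, 37938, 2735, 57768],
      "elevated": [2446, 28938, 2303, 41984],
      "severe": [1079, 8885, 166, 2452]
    },
    "combined": [6980, 86237, 5382, 108148]
  },
  "week_bins": {
    "1": {"1": 3888, "2": 1007, "3": 328, "4": 159},
    "2": {"1": 3626, "2": 1690, "3": 1019, "4": 645}
  }
}
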