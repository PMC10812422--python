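{
  "version": "1.0",
  "notes": "Hourly-count bins for scratch/lick/swallow and daily sleep-hour bands. Level 0 is the normal band for every behavior. Open-ended top bins ('upper': null) are closed as >= lower. 'alt_trouble_cutoff_h' preserves the 20%-reduction sleep cutoff (9.6 h) for users preferring a four-band sleep reading.",
  "scratch": {
    "unit": "events/hour",
    "bins": [
      {"label": "average", "level": 0, "lower": 0, "upper": 52},
      {"label": "sometimes", "level": 1, "lower": 53, "upper": 119},
      {"label": "often", "level": 2, "lower": 120, "upper": 299},
      {"label": "serious", "level": 3, "lower": 300, "upper": null}
    ]
  },
  "lick": {
    "unit": "events/hour",
    "bins": [
      {"label": "average", "level": 0, "lower": 0, "upper": 7},
      {"label": "sometimes", "level": 1, "lower": 8, "upper": 19},
      {"label": "often", "level": 2, "lower": 20, "upper": 43},
      {"label": "serious", "level": 3, "lower": 44, "upper": null}
    ]
  },
  "swallow": {
    "unit": "events/hour",
    "bins": [
      {"label": "below average", "level": 1, "lower": 0, "upper": 30},
      {"label": "average", "level": 0, "lower": 31, "upper": 59},
      {"label": "above average", "level": 2, "lower": 60, "upper": null}
    ]
  },
  "sleep": {
    "unit": "hours/day",
    "alt_trouble_cutoff_h": 9.6,
    "bands": [
      {"label": "strikingly little", "level": 2, "lower": 0.0, "upper": 3.6},
      {"label": "a little bit of trouble", "level": 1, "lower": 3.6, "upper": 12.0},
      {"label": "deep sleep", "level": 0, "lower": 12.0, "upper": 24.0}
    ]
  }
}
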