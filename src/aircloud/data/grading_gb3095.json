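{
  "name": "GB 3095-2012 / HJ 633-2012 daily grading table",
  "levels": ["Good", "Moderate", "Lightly Polluted", "Moderately Polluted", "Heavily Polluted"],
  "index_scale": {"upper_limits": [50, 100, 150, 200, 300], "unit": "index points"},
  "indicators": {
    "PM2.5": {"unit": "ug/m3", "upper_limits": [35, 75, 115, 150, 250]},
    "PM10":  {"unit": "ug/m3", "upper_limits": [50, 150, 250, 350, 420]},
    "SO2":   {"unit": "ug/m3", "upper_limits": [50, 150, 475, 800, 1600]},
    "CO":    {"unit": "mg/m3", "upper_limits": [2, 4, 14, 24, 36]},
    "NO2":   {"unit": "ug/m3", "upper_limits": [40, 80, 180, 280, 565]},
    "O3":    {"unit": "ug/m3", "upper_limits": [100, 160, 215, 265, 800]}
  }
}
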