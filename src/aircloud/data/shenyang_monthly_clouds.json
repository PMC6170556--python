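{
  "description": "Published monthly cloud models (Ex, En, He) and assessed levels for Shenyang, Nov 2016 - Oct 2017. Classification fixtures; the underlying daily series are not distributed.",
  "indicators": ["PM2.5", "PM10", "SO2", "CO", "NO2", "O3"],
  "months": [
    {"month": "2016-11",
     "clouds": {"PM2.5": [73.50, 39.93, 23.36], "PM10": [107.45, 48.57, 29.08], "SO2": [71.36, 29.07, 12.65], "CO": [1.01, 0.38, 0.08], "NO2": [48.46, 11.17, 2.21], "O3": [57.90, 12.81, 6.10]},
     "levels": {"PM2.5": 2, "PM10": 2, "SO2": 2, "CO": 1, "NO2": 2, "O3": 1}},
    {"month": "2016-12",
     "clouds": {"PM2.5": [95.65, 53.36, 10.47], "PM10": [133.52, 63.70, 7.35], "SO2": [95.65, 39.70, 7.42], "CO": [1.44, 0.65, 0.22], "NO2": [57.42, 16.10, 6.21], "O3": [39.77, 14.41, 2.56]},
     "levels": {"PM2.5": 3, "PM10": 2, "SO2": 2, "CO": 1, "NO2": 2, "O3": 1}},
    {"month": "2017-01",
     "clouds": {"PM2.5": [88.84, 56.46, 9.74], "PM10": [128.03, 64.97, 12.23], "SO2": [98.77, 41.92, 16.19], "CO": [1.39, 0.69, 0.26], "NO2": [54.81, 20.87, 8.33], "O3": [50, 16.17, 4.49]},
     "levels": {"PM2.5": 3, "PM10": 2, "SO2": 2, "CO": 1, "NO2": 2, "O3": 1}},
    {"month": "2017-02",
     "clouds": {"PM2.5": [66.18, 37.95, 6.10], "PM10": [95.75, 42.97, 3.16], "SO2": [70.96, 31.64, 5.87], "CO": [1.07, 0.52, 0.02], "NO2": [46.14, 16.38, 6.26], "O3": [75.68, 12.64, 7.94]},
     "levels": {"PM2.5": 2, "PM10": 2, "SO2": 2, "CO": 1, "NO2": 2, "O3": 1}},
    {"month": "2017-03",
     "clouds": {"PM2.5": [83.03, 45.81, 16.47], "PM10": [124.23, 55.18, 17.52], "SO2": [54.10, 23.10, 8.11], "CO": [1.02, 0.42, 0.12], "NO2": [53.71, 17.76, 6.26], "O3": [109.35, 18.60, 6.92]},
     "levels": {"PM2.5": 3, "PM10": 2, "SO2": 2, "CO": 1, "NO2": 2, "O3": 2}},
    {"month": "2017-04",
     "clouds": {"PM2.5": [47.87, 24.53, 8.89], "PM10": [104.13, 34.35, 10.86], "SO2": [23.93, 11.27, 3.23], "CO": [0.77, 0.28, 0.07], "NO2": [36.37, 9.23, 0.97], "O3": [119.63, 29.06, 5.34]},
     "levels": {"PM2.5": 2, "PM10": 2, "SO2": 1, "CO": 1, "NO2": 1, "O3": 2}},
    {"month": "2017-05",
     "clouds": {"PM2.5": [40.94, 15.04, 4.08], "PM10": [107.03, 60.05, 32.71], "SO2": [14.13, 4.86, 1.78], "CO": [0.63, 0.20, 0.02], "NO2": [29.13, 8.11, 0.62], "O3": [144.16, 47.51, 9.38]},
     "levels": {"PM2.5": 2, "PM10": 2, "SO2": 1, "CO": 1, "NO2": 1, "O3": 2}},
    {"month": "2017-06",
     "clouds": {"PM2.5": [34.33, 14.12, 3.46], "PM10": [64.00, 24.06, 6.25], "SO2": [18.30, 6.37, 0.93], "CO": [0.77, 0.30, 0.05], "NO2": [33.17, 8.06, 1.35], "O3": [156.13, 52.78, 13.02]},
     "levels": {"PM2.5": 1, "PM10": 2, "SO2": 1, "CO": 1, "NO2": 1, "O3": 2}},
    {"month": "2017-07",
     "clouds": {"PM2.5": [30.94, 10.37, 2.33], "PM10": [51.97, 15.16, 0.93], "SO2": [12.23, 5.40, 0.78], "CO": [0.74, 0.19, 0.07], "NO2": [27.58, 10.45, 2.11], "O3": [155.23, 38.49, 12.38]},
     "levels": {"PM2.5": 1, "PM10": 2, "SO2": 1, "CO": 1, "NO2": 1, "O3": 2}},
    {"month": "2017-08",
     "clouds": {"PM2.5": [25.03, 9.10, 6.32], "PM10": [46.00, 14.64, 7.64], "SO2": [14.97, 4.49, 2.03], "CO": [0.83, 0.26, 0.10], "NO2": [29.74, 6.38, 3.59], "O3": [106.87, 38.48, 12.15]},
     "levels": {"PM2.5": 1, "PM10": 1, "SO2": 1, "CO": 1, "NO2": 1, "O3": 2}},
    {"month": "2017-09",
     "clouds": {"PM2.5": [31.97, 12.32, 1.96], "PM10": [62.20, 16.24, 2.60], "SO2": [22.57, 7.02, 1.78], "CO": [0.93, 0.29, 0.08], "NO2": [37.93, 7.51, 0.82], "O3": [102.93, 32.17, 11.98]},
     "levels": {"PM2.5": 1, "PM10": 2, "SO2": 1, "CO": 1, "NO2": 1, "O3": 2}},
    {"month": "2017-10",
     "clouds": {"PM2.5": [51.94, 33.77, 1.28], "PM10": [88.90, 44.89, 6.90], "SO2": [24.74, 12.46, 3.97], "CO": [1.10, 0.60, 0.13], "NO2": [47.74, 18.87, 4.93], "O3": [72.94, 23.59, 8.55]},
     "levels": {"PM2.5": 2, "PM10": 2, "SO2": 1, "CO": 1, "NO2": 2, "O3": 1}}
  ]
}
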