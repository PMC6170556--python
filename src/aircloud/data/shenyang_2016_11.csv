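date,PM2.5,PM10,SO2,CO,NO2,O3
2016-11-01,55.5,94.6,87.3,1.071,48.1,57
2016-11-02,48.2,85.3,90.3,1.229,57.8,64
2016-11-03,64.2,107.8,102.7,1.138,63,32
2016-11-04,120.9,184.9,125,1.554,63.2,47
2016-11-05,220.2,274.4,47.1,1.188,54.7,100
2016-11-06,95.8,116.2,53,0.683,47.3,74
2016-11-07,169.4,191.5,48.9,0.946,49.9,89
2016-11-08,60.3,74.3,55.3,0.596,46.2,60
2016-11-09,66.7,99,98.6,1.146,58.9,44
2016-11-10,31.5,52,52.8,0.754,35.8,56
2016-11-11,48.1,67.9,51.3,0.679,41.7,47
2016-11-12,50.2,80.9,63.8,0.809,47.9,57
2016-11-13,64.2,105.4,83.9,1.154,47.8,68
2016-11-14,48.7,109.9,34.6,0.625,28.1,69
2016-11-15,33.6,62.4,47.6,0.578,39.4,56
2016-11-16,86.7,134.7,104.3,1.47,58.4,40
2016-11-17,179.5,247.8,108.5,1.975,71.9,62
2016-11-18,82.4,125.7,55,0.957,41.4,70
2016-11-19,36.8,47.9,32.2,0.563,28.4,50
2016-11-20,33.6,44.2,54.6,0.596,39.5,55
2016-11-21,19.7,32.6,40,0.479,27.5,56
2016-11-22,20.8,36,40.6,0.488,29,60
2016-11-23,51,81,82,0.908,49.8,48
2016-11-24,74,111.8,88.8,1.267,54.2,62
2016-11-25,66.5,108.9,107.4,1.546,56,48
2016-11-26,106.5,157.1,70.3,1.367,55.8,38
2016-11-27,77.5,119.7,59,1.221,47.2,70
2016-11-28,65.6,104.4,89.9,1.246,59.3,47
2016-11-29,68.7,106.7,106.5,1.033,59.3,58
2016-11-30,58.3,88.4,58.5,1.125,46.4,53
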