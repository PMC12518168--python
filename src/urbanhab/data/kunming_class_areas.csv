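period,scenario,unsuitable,low,medium,high
1970-2000,baseline,76.26,201.83,92.54,88.38
2021-2040,SSP1-2.6,88.95,134.37,96.95,138.73
2021-2040,SSP2-4.5,114.13,164.71,63.46,116.70
2021-2040,SSP5-8.5,100.02,127.05,106.52,125.41
2041-2060,SSP1-2.6,129.66,153.40,61.55,114.39
2041-2060,SSP2-4.5,103.10,174.70,68.42,112.78
2041-2060,SSP5-8.5,130.15,143.44,49.11,136.31
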