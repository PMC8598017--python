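{
  "r_max_true": 0.08,
  "K_true": 21000.0,
  "z": 2.39,
  "onset_year": 1904,
  "peak_catch": 1275.0,
  "ramp_up": 6,
  "ramp_down": 50,
  "end_catch_year": 1965,
  "start_year": 1901,
  "end_year": 2040,
  "obs_abundance": [
    [
      2005,
      0.17
    ],
    [
      2008,
      0.084
    ],
    [
      2012,
      0.071
    ]
  ],
  "obs_growth": [
    [
      1995,
      1998,
      0.446
    ],
    [
      2002,
      2011,
      0.115
    ]
  ],
  "seed": 20210
}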