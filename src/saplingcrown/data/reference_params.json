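{
  "form": "power_exp_full",
  "comment": "Published power-exponential crown-profile coefficient estimates (a1..a5) for naturally regenerated Pinus tabuliformis saplings, by strip type and fit (OLS and selected nonlinear quantile-regression rows). Reference evaluation settings: crown ratio fixed at 0.80, DBH at 2.0 cm (approximate sample means).",
  "crown_ratio_reference": 0.80,
  "dbh_reference_cm": 2.0,
  "strips": {
    "shelterwood_cut": {
      "selected": "q0.88",
      "fits": {
        "ols":   [0.3848, 0.6002, 1.3131, -0.4378, -1.6558],
        "q0.75": [0.3543, 0.5363, 1.2589, -0.5247, -1.1415],
        "q0.85": [0.3881, 0.4892, 1.2204, -0.5747, -0.9509],
        "q0.95": [0.5648, 0.3607, 1.0896, -0.5414, -0.7556],
        "q0.99": [0.6379, 0.2500, 0.8087, -0.4039, -0.3635],
        "q0.88": [0.4030, 0.4751, 1.1811, -0.5538, -0.9125]
      }
    },
    "uncut": {
      "selected": "q0.92",
      "fits": {
        "ols":   [1.1287, 0.5288, 1.4591, -0.0522, -2.3823],
        "q0.75": [0.6884, 0.5346, 1.1902, -0.0289, -1.6889],
        "q0.85": [0.8041, 0.4941, 1.1184, 0.0141, -1.6638],
        "q0.95": [1.2189, 0.2915, 1.0042, -0.0639, -1.3446],
        "q0.99": [0.9989, 0.3235, 0.8906, -0.0947, -0.9920],
        "q0.92": [1.2834, 0.3950, 1.2543, -0.1097, -1.8092]
      }
    }
  }
}
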