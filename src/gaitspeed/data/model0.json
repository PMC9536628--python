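{
  "name": "model0",
  "response_units": "cm/s",
  "description": "Baseline gait-speed regression: age, sex (male=1, female=2), cadence, VHD, foot length.",
  "intercept": -113.2,
  "coefficients": {
    "age": -0.388,
    "sex": 3.06,
    "cadence": 1.17,
    "vhd": 12.1,
    "foot_length": 3.25
  }
}
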