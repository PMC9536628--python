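{
  "name": "model1",
  "response_units": "cm/s",
  "description": "Extended gait-speed regression: adds body weight and trunk roll/yaw excursions; drops sex.",
  "intercept": -106.0,
  "coefficients": {
    "age": -0.328,
    "cadence": 1.10,
    "vhd": 10.1,
    "foot_length": 3.29,
    "weight": -0.115,
    "roll_angle": 1.01,
    "yaw_angle": 0.647
  }
}
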