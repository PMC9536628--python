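{
  "name": "model2",
  "response_units": "cm/s",
  "description": "Normalized-step-length (NSL) subgroup-specific gait-speed regressions. Subgroup assignment: Model-1 speed -> step length -> NSL -> nearest centroid.",
  "base": "model1",
  "centroids": [0.324, 0.370, 0.418],
  "centroid_sds": [0.019, 0.014, 0.019],
  "submodels": {
    "short": {
      "name": "model2_short",
      "response_units": "cm/s",
      "intercept": -95.6,
      "coefficients": {
        "age": -0.462,
        "cadence": 1.06,
        "vhd": 13.3,
        "foot_length": 3.24,
        "weight": -0.154,
        "roll_angle": 1.27,
        "yaw_angle": 0.550
      }
    },
    "medium": {
      "name": "model2_medium",
      "response_units": "cm/s",
      "intercept": -117.8,
      "coefficients": {
        "age": -0.327,
        "cadence": 1.14,
        "vhd": 11.8,
        "foot_length": 3.26,
        "weight": -0.122,
        "roll_angle": 1.14,
        "yaw_angle": 0.828
      }
    },
    "long": {
      "name": "model2_long",
      "response_units": "cm/s",
      "intercept": -121.4,
      "coefficients": {
        "age": -0.272,
        "cadence": 1.15,
        "vhd": 9.90,
        "foot_length": 3.68,
        "weight": -0.179,
        "roll_angle": 1.04,
        "yaw_angle": 0.620
      }
    }
  }
}
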