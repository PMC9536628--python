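{
  "description": "Marginal summaries (mean, sd) of the reference cohort of community-dwelling healthy older adults used to parameterize the synthetic cohort generator, plus the same summaries within the three normalized-step-length subgroups. Units: age yr, height/foot_length cm, weight kg, cadence steps/min, vhd cm, roll/yaw deg, gait_speed cm/s.",
  "all": {
    "n": 759,
    "female_fraction": 0.555,
    "age": [73.9, 4.8],
    "height": [159.8, 8.1],
    "weight": [61.6, 9.0],
    "foot_length": [23.4, 1.4],
    "cadence": [115.5, 9.4],
    "vhd": [3.29, 0.77],
    "roll_angle": [6.4, 2.4],
    "yaw_angle": [12.2, 3.6],
    "gait_speed": [114.4, 17.9]
  },
  "subgroups": {
    "short": {
      "n": 188,
      "female_fraction": 0.514,
      "nsl": [0.324, 0.019],
      "age": [76.7, 5.1],
      "height": [159.7, 7.9],
      "weight": [62.3, 8.6],
      "foot_length": [23.0, 1.2],
      "cadence": [109.9, 9.8],
      "vhd": [2.53, 0.40],
      "roll_angle": [4.92, 1.67],
      "yaw_angle": [9.56, 2.62],
      "gait_speed": [95.1, 13.7]
    },
    "medium": {
      "n": 378,
      "female_fraction": 0.572,
      "nsl": [0.370, 0.014],
      "age": [73.2, 4.3],
      "height": [160.4, 8.2],
      "weight": [62.0, 9.0],
      "foot_length": [23.5, 1.4],
      "cadence": [116.4, 8.2],
      "vhd": [3.24, 0.47],
      "roll_angle": [6.42, 2.28],
      "yaw_angle": [12.07, 2.93],
      "gait_speed": [115.5, 12.2]
    },
    "long": {
      "n": 193,
      "female_fraction": 0.566,
      "nsl": [0.418, 0.019],
      "age": [72.6, 4.3],
      "height": [158.8, 8.2],
      "weight": [60.1, 9.3],
      "foot_length": [23.7, 1.4],
      "cadence": [119.2, 8.7],
      "vhd": [4.14, 0.69],
      "roll_angle": [7.79, 2.53],
      "yaw_angle": [15.15, 3.46],
      "gait_speed": [130.9, 12.3]
    }
  }
}
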