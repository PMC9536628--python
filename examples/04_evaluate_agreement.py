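"""Score model predictions against gold-standard reference speeds.

On a synthetic cohort with known 5 cm/s measurement noise, the agreement
table reports mean percent error (ME), mean absolute percent error
(MAE), RMSE in cm/s and the intraclass correlation ICC(2,1), overall and
within slow/medium/fast strata (mean +/- 1 SD of the reference speed).
"""

import numpy as np

from gaitspeed import (
    GaitFeatures,
    ParticipantProfile,
    evaluate_models,
    generate_cohort,
    load_model,
    predict_model2,
)

model2 = load_model("model2")
cohort = generate_cohort(n=1000, generator_model=model2, residual_sd=5.0, seed=11)

estimates = []
for rec in cohort.to_dict(orient="records"):
    feats = GaitFeatures(cadence=rec["cadence"], vhd=rec["vhd"],
                         roll_angle=rec["roll_angle"], yaw_angle=rec["yaw_angle"],
                         n_steps=0, mean_step_time=60 / rec["cadence"])
    profile = ParticipantProfile(age=rec["age"], sex=int(rec["sex"]),
                                 height=rec["height"], weight=rec["weight"],
                                 foot_length=rec["foot_length"])
    estimates.append(predict_model2(profile, feats, model2).speed)

table = evaluate_models({"model2": np.array(estimates)},
                        cohort["reference_speed"].to_numpy())
cols = ["stratum", "n", "me_pct", "mae_pct", "rmse_cm_s", "icc"]
print(table[cols].round(3).to_string(index=False))
print("RMSE near the injected 5 cm/s noise and ICC > 0.9 mean the estimator "
      "adds essentially no error beyond the reference measurement noise.")
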