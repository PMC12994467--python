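{
 "schema": "pronecg.vcg_regression_model.v1",
 "comment": "Published cohort regression coefficients for the prone-ECG to orthogonal-lead (VCG) model. Predictor scaling and intercepts were not reported with the source table; the fixture is flagged scale-unknown and must not be used for amplitude-accuracy claims. Freshly fitted models are the validated path.",
 "predictors": ["Lead I", "Lead II", "Lead III", "Lead aVR", "Lead aVL", "Lead aVF", "Lead V1", "Lead V2", "Lead V3", "Lead V4", "Lead V5", "Lead V6", "Male", "Age", "Height", "Weight"],
 "targets": ["X", "Y", "Z"],
 "B": [
  [-0.603, 0.730, -1.413],
  [1.123, -1.313, 0.457],
  [-0.121, -0.390, 0.726],
  [0.238, -2.091, 2.028],
  [0.365, -0.847, 1.707],
  [0.045, 0.374, -0.181],
  [0.065, -0.119, 0.709],
  [0.042, 0.244, -0.397],
  [-0.657, -0.626, 2.185],
  [0.552, -0.181, -1.317],
  [0.055, -0.191, 1.561],
  [0.513, 0.860, -1.166],
  [0.067, 0.134, -0.143],
  [-0.004, 0.333, -0.581],
  [0.325, -0.098, -0.237],
  [-0.394, -0.376, 0.943]
 ],
 "intercept": [0.0, 0.0, 0.0],
 "r2": {"X": 0.968, "Y": 0.968, "Z": 0.845},
 "n": 0,
 "scale_note": "scale-unknown: predictor standardisation and intercepts unreported in the source; do not use for amplitude claims"
}
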