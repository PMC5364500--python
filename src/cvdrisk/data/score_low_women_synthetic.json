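{
 "baseline_survival": {},
 "category_labels": [
  "low",
  "intermediate",
  "high"
 ],
 "diabetes_multiplier": {
  "female": 5.0,
  "male": 3.0
 },
 "family": "weibull_score",
 "metadata": {
  "notes": "synthetic placeholder Weibull parameters of plausible magnitude; replace with the published SCORE values",
  "synthetic": true
 },
 "model_id": "SCORE-low",
 "native_horizon": 10.0,
 "schema_version": 1,
 "sex": "female",
 "thresholds": [
  0.01,
  0.05
 ],
 "units": {
  "age": "years",
  "sbp": "mmHg",
  "total_cholesterol": "mmol/L"
 },
 "weibull": {
  "chd": {
   "alpha": -23.5,
   "beta_chol": 0.24,
   "beta_sbp": 0.018,
   "beta_smoker": 0.7,
   "p": 4.7
  },
  "non_chd": {
   "alpha": -27.5,
   "beta_chol": 0.14,
   "beta_sbp": 0.022,
   "beta_smoker": 0.55,
   "p": 5.6
  },
  "region": "low"
 }
}
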