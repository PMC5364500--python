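{
 "baseline_survival": {
  "5": 0.993261
 },
 "category_labels": [
  "low",
  "intermediate",
  "high"
 ],
 "family": "cox_form",
 "mean_lp": 30.74361,
 "metadata": {
  "provenance": "recalibrated to the Henan rural cohort"
 },
 "model_id": "simplified-FRS",
 "native_horizon": 5.0,
 "schema_version": 1,
 "sex": "female",
 "terms": [
  {
   "coefficient": 4.0899,
   "covariate": "age",
   "label": "Ln of Age (y)",
   "transform": "log"
  },
  {
   "coefficient": -0.6864,
   "covariate": "bmi",
   "label": "Ln of BMI (kg/m2)",
   "transform": "log"
  },
  {
   "coefficient": 3.4689,
   "condition": {
    "covariate": "bp_treated",
    "equals": false
   },
   "covariate": "sbp",
   "label": "Ln of SBP if not treated (mm Hg)",
   "transform": "log"
  },
  {
   "coefficient": 3.4942,
   "condition": {
    "covariate": "bp_treated",
    "equals": true
   },
   "covariate": "sbp",
   "label": "Ln of SBP if treated (mm Hg)",
   "transform": "log"
  },
  {
   "coefficient": -3.0307,
   "covariate": "current_smoker",
   "label": "Smoking",
   "transform": "identity"
  },
  {
   "coefficient": 0.7639,
   "covariate": "diabetes",
   "label": "Diabetes",
   "transform": "identity"
  }
 ],
 "thresholds": [
  0.1,
  0.2
 ],
 "units": {
  "age": "years",
  "bmi": "kg/m2",
  "sbp": "mmHg"
 }
}
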