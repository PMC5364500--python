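{
 "baseline_survival": {
  "5": 0.9914698
 },
 "category_labels": [
  "low",
  "intermediate",
  "high"
 ],
 "family": "cox_form",
 "mean_lp": 32.45731,
 "metadata": {
  "provenance": "recalibrated to the Henan rural cohort"
 },
 "model_id": "general-FRS",
 "native_horizon": 5.0,
 "schema_version": 1,
 "sex": "male",
 "terms": [
  {
   "coefficient": 5.1215,
   "covariate": "age",
   "label": "Ln of Age (y)",
   "transform": "log"
  },
  {
   "coefficient": -0.2727,
   "covariate": "total_cholesterol",
   "label": "Ln of Total Cholesterol (mg/dL)",
   "transform": "log"
  },
  {
   "coefficient": -0.4596,
   "covariate": "hdl",
   "label": "Ln HDL-C (mg/dL)",
   "transform": "log"
  },
  {
   "coefficient": 3.2282,
   "condition": {
    "covariate": "bp_treated",
    "equals": false
   },
   "covariate": "sbp",
   "label": "Ln of SBP if not treated (mm Hg)",
   "transform": "log"
  },
  {
   "coefficient": 3.3088,
   "condition": {
    "covariate": "bp_treated",
    "equals": true
   },
   "covariate": "sbp",
   "label": "Ln of SBP if treated (mm Hg)",
   "transform": "log"
  },
  {
   "coefficient": -0.4882,
   "covariate": "current_smoker",
   "label": "Smoking",
   "transform": "identity"
  },
  {
   "coefficient": 0.6518,
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
  "hdl": "mg/dL",
  "sbp": "mmHg",
  "total_cholesterol": "mg/dL"
 }
}
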