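{
 "baseline_survival": {
  "5": 0.9914698
 },
 "category_labels": [
  "<7.5%",
  "7.5-9.9%",
  "10.0-19.9%",
  ">=20%"
 ],
 "family": "cox_form",
 "mean_lp": 32.45731,
 "metadata": {
  "anomaly": "published PCE-AA men column coincides numerically with the general-FRS men column; transcribed as printed",
  "provenance": "recalibrated to the Henan rural cohort"
 },
 "model_id": "PCE-AA",
 "native_horizon": 5.0,
 "schema_version": 1,
 "sex": "male",
 "terms": [
  {
   "coefficient": 5.1215,
   "covariate": "age",
   "label": "Ln Age (y)",
   "transform": "log"
  },
  {
   "coefficient": -0.2727,
   "covariate": "total_cholesterol",
   "label": "Ln Total Cholesterol (mg/dL)",
   "transform": "log"
  },
  {
   "coefficient": -0.4596,
   "covariate": "hdl",
   "label": "Ln HDL-C (mg/dL)",
   "transform": "log"
  },
  {
   "coefficient": 3.3088,
   "condition": {
    "covariate": "bp_treated",
    "equals": true
   },
   "covariate": "sbp",
   "label": "Ln Treated SBP (mm Hg)",
   "transform": "log"
  },
  {
   "coefficient": 3.2282,
   "condition": {
    "covariate": "bp_treated",
    "equals": false
   },
   "covariate": "sbp",
   "label": "Ln Untreated SBP (mm Hg)",
   "transform": "log"
  },
  {
   "coefficient": -0.4882,
   "covariate": "current_smoker",
   "label": "Current Smoker (1 = Yes, 0 = No)",
   "transform": "identity"
  },
  {
   "coefficient": 0.6518,
   "covariate": "diabetes",
   "label": "Diabetes (1 = Yes, 0 = No)",
   "transform": "identity"
  }
 ],
 "thresholds": [
  0.075,
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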