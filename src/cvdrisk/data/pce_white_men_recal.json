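{
 "baseline_survival": {
  "5": 0.9915944
 },
 "category_labels": [
  "<7.5%",
  "7.5-9.9%",
  "10.0-19.9%",
  ">=20%"
 ],
 "family": "cox_form",
 "mean_lp": -19.22938,
 "metadata": {
  "provenance": "recalibrated to the Henan rural cohort"
 },
 "model_id": "PCE-white",
 "native_horizon": 5.0,
 "schema_version": 1,
 "sex": "male",
 "terms": [
  {
   "coefficient": -7.6938,
   "covariate": "age",
   "label": "Ln Age (y)",
   "transform": "log"
  },
  {
   "coefficient": -20.8736,
   "covariate": "total_cholesterol",
   "label": "Ln Total Cholesterol (mg/dL)",
   "transform": "log"
  },
  {
   "coefficient": 5.0969,
   "factors": [
    {
     "covariate": "age",
     "transform": "log"
    },
    {
     "covariate": "total_cholesterol",
     "transform": "log"
    }
   ],
   "label": "Ln Age x Ln Total Cholesterol",
   "transform": "product"
  },
  {
   "coefficient": 14.2871,
   "covariate": "hdl",
   "label": "Ln HDL-C (mg/dL)",
   "transform": "log"
  },
  {
   "coefficient": -3.6424,
   "factors": [
    {
     "covariate": "age",
     "transform": "log"
    },
    {
     "covariate": "hdl",
     "transform": "log"
    }
   ],
   "label": "Ln Age x Ln HDL-C",
   "transform": "product"
  },
  {
   "coefficient": 3.3128,
   "condition": {
    "covariate": "bp_treated",
    "equals": true
   },
   "covariate": "sbp",
   "label": "Ln Treated SBP (mm Hg)",
   "transform": "log"
  },
  {
   "coefficient": 3.2339,
   "condition": {
    "covariate": "bp_treated",
    "equals": false
   },
   "covariate": "sbp",
   "label": "Ln Untreated SBP (mm Hg)",
   "transform": "log"
  },
  {
   "coefficient": -2.9244,
   "covariate": "current_smoker",
   "label": "Current Smoker (1 = Yes, 0 = No)",
   "transform": "identity"
  },
  {
   "coefficient": 0.6021,
   "factors": [
    {
     "covariate": "age",
     "transform": "log"
    },
    {
     "covariate": "current_smoker",
     "transform": "identity"
    }
   ],
   "label": "Ln Age x Current Smoker",
   "transform": "product"
  },
  {
   "coefficient": 0.6608,
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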