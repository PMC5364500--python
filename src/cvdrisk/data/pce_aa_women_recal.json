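{
 "baseline_survival": {
  "5": 0.9931984
 },
 "category_labels": [
  "<7.5%",
  "7.5-9.9%",
  "10.0-19.9%",
  ">=20%"
 ],
 "family": "cox_form",
 "mean_lp": -162.2403,
 "metadata": {
  "provenance": "recalibrated to the Henan rural cohort"
 },
 "model_id": "PCE-AA",
 "native_horizon": 5.0,
 "schema_version": 1,
 "sex": "female",
 "terms": [
  {
   "coefficient": -42.607,
   "covariate": "age",
   "label": "Ln Age (y)",
   "transform": "log"
  },
  {
   "coefficient": -0.9533,
   "covariate": "total_cholesterol",
   "label": "Ln Total Cholesterol (mg/dL)",
   "transform": "log"
  },
  {
   "coefficient": 0.5844,
   "covariate": "hdl",
   "label": "Ln HDL-C (mg/dL)",
   "transform": "log"
  },
  {
   "coefficient": -0.2728,
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
   "coefficient": -34.6531,
   "condition": {
    "covariate": "bp_treated",
    "equals": true
   },
   "covariate": "sbp",
   "label": "Ln Treated SBP (mm Hg)",
   "transform": "log"
  },
  {
   "coefficient": 9.4585,
   "condition": {
    "covariate": "bp_treated",
    "equals": true
   },
   "factors": [
    {
     "covariate": "age",
     "transform": "log"
    },
    {
     "covariate": "sbp",
     "transform": "log"
    }
   ],
   "label": "Ln Age x Ln Treated SBP",
   "transform": "product"
  },
  {
   "coefficient": -36.7922,
   "condition": {
    "covariate": "bp_treated",
    "equals": false
   },
   "covariate": "sbp",
   "label": "Ln Untreated SBP (mm Hg)",
   "transform": "log"
  },
  {
   "coefficient": 9.9831,
   "condition": {
    "covariate": "bp_treated",
    "equals": false
   },
   "factors": [
    {
     "covariate": "age",
     "transform": "log"
    },
    {
     "covariate": "sbp",
     "transform": "log"
    }
   ],
   "label": "Ln Age x Ln Untreated SBP",
   "transform": "product"
  },
  {
   "coefficient": -3.874,
   "covariate": "current_smoker",
   "label": "Current Smoker (1 = Yes, 0 = No)",
   "transform": "identity"
  },
  {
   "coefficient": 0.7789,
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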