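{
 "baseline_survival": {
  "5": 0.9934143
 },
 "category_labels": [
  "<7.5%",
  "7.5-9.9%",
  "10.0-19.9%",
  ">=20%"
 ],
 "family": "cox_form",
 "mean_lp": -51.67933,
 "metadata": {
  "provenance": "recalibrated to the Henan rural cohort"
 },
 "model_id": "PCE-white",
 "native_horizon": 5.0,
 "schema_version": 1,
 "sex": "female",
 "terms": [
  {
   "coefficient": -22.3973,
   "covariate": "age",
   "label": "Ln Age (y)",
   "transform": "log"
  },
  {
   "coefficient": 1.7899,
   "factors": [
    {
     "covariate": "age",
     "transform": "log"
    },
    {
     "covariate": "age",
     "transform": "log"
    }
   ],
   "label": "Ln Age, Squared",
   "transform": "product"
  },
  {
   "coefficient": 15.0642,
   "covariate": "total_cholesterol",
   "label": "Ln Total Cholesterol (mg/dL)",
   "transform": "log"
  },
  {
   "coefficient": 3.5038,
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
   "coefficient": 5.1555,
   "covariate": "hdl",
   "label": "Ln HDL-C (mg/dL)",
   "transform": "log"
  },
  {
   "coefficient": -1.4068,
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
   "coefficient": 3.4666,
   "condition": {
    "covariate": "bp_treated",
    "equals": true
   },
   "covariate": "sbp",
   "label": "Ln Treated SBP (mm Hg)",
   "transform": "log"
  },
  {
   "coefficient": 3.4459,
   "condition": {
    "covariate": "bp_treated",
    "equals": false
   },
   "covariate": "sbp",
   "label": "Ln Untreated SBP (mm Hg)",
   "transform": "log"
  },
  {
   "coefficient": 17.8261,
   "covariate": "current_smoker",
   "label": "Current Smoker (1 = Yes, 0 = No)",
   "transform": "identity"
  },
  {
   "coefficient": -5.6228,
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
   "coefficient": 0.7707,
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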