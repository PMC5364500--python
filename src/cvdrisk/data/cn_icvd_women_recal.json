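{
 "baseline_survival": {
  "5": 0.9931033
 },
 "category_labels": [
  "low",
  "intermediate",
  "high"
 ],
 "family": "cox_form",
 "mean_lp": 3.976495,
 "metadata": {
  "notes": "Referent bands carry coefficient 0; bands are half-open [lo, hi)",
  "provenance": "recalibrated to the Henan rural cohort"
 },
 "model_id": "CN-ICVD",
 "native_horizon": 5.0,
 "schema_version": 1,
 "sex": "female",
 "terms": [
  {
   "coefficient": 0.0878,
   "covariate": "age",
   "label": "Age, y",
   "transform": "identity"
  },
  {
   "bands": [
    {
     "coefficient": -0.313,
     "hi": 120.0
    },
    {
     "coefficient": 0.0,
     "hi": 130.0,
     "lo": 120.0
    },
    {
     "coefficient": 0.1822,
     "hi": 140.0,
     "lo": 130.0
    },
    {
     "coefficient": 0.456,
     "hi": 160.0,
     "lo": 140.0
    },
    {
     "coefficient": 0.9871,
     "hi": 180.0,
     "lo": 160.0
    },
    {
     "coefficient": 1.8207,
     "lo": 180.0
    }
   ],
   "covariate": "sbp",
   "label": "SBP, mm Hg",
   "transform": "band"
  },
  {
   "bands": [
    {
     "coefficient": 0.0,
     "hi": 24.0
    },
    {
     "coefficient": -0.0624,
     "lo": 24.0
    }
   ],
   "covariate": "bmi",
   "label": "BMI, kg/m2",
   "transform": "band"
  },
  {
   "bands": [
    {
     "coefficient": 0.0,
     "hi": 3.62
    },
    {
     "coefficient": -0.6806,
     "hi": 5.17,
     "lo": 3.62
    },
    {
     "coefficient": -0.8578,
     "lo": 5.17
    }
   ],
   "covariate": "total_cholesterol",
   "label": "Total cholesterol, mmol/L",
   "transform": "band"
  },
  {
   "coefficient": -3.3481,
   "covariate": "current_smoker",
   "label": "Current smoker, yes/no",
   "transform": "identity"
  },
  {
   "coefficient": 0.8233,
   "covariate": "diabetes",
   "label": "Diabetes, yes/no",
   "transform": "identity"
  }
 ],
 "thresholds": [
  0.05,
  0.1
 ],
 "units": {
  "age": "years",
  "bmi": "kg/m2",
  "sbp": "mmHg",
  "total_cholesterol": "mmol/L"
 }
}
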