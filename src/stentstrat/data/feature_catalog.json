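{
  "clinical": {
    "aha_lesion_class": {"kind": "categorical", "levels": ["A", "B1", "B2", "C"], "sets": ["C1", "C2", "C3"]},
    "angina": {"kind": "binary", "sets": ["C1", "C2", "C3"]},
    "ccs_grade": {"kind": "continuous", "sets": ["C1", "C2", "C3"]},
    "angulation": {"kind": "binary", "sets": ["C1", "C3"]},
    "bmi": {"kind": "continuous", "sets": ["C1", "C2", "C3"]},
    "hypercholesterolemia": {"kind": "binary", "sets": ["C1", "C2", "C3"]},
    "dissection": {"kind": "binary", "sets": ["C1", "C3"]},
    "ejection_fraction": {"kind": "continuous", "sets": ["C1", "C2", "C3"]},
    "eccentric_lesion": {"kind": "binary", "sets": ["C1", "C2", "C3"]},
    "family_history": {"kind": "binary", "sets": ["C1", "C2", "C3"]},
    "history_bypass": {"kind": "binary", "sets": ["C1", "C2", "C3"]},
    "history_intervention": {"kind": "binary", "sets": ["C1", "C2", "C3"]},
    "history_mi": {"kind": "binary", "sets": ["C1", "C2", "C3"]},
    "hypertension": {"kind": "binary", "sets": ["C1", "C2", "C3"]},
    "lesion_length": {"kind": "continuous", "sets": ["C1", "C2", "C3"]},
    "lv_function": {"kind": "categorical", "levels": ["normal", "moderately_reduced", "severely_reduced"], "sets": ["C1", "C2"]},
    "min_lumen_diameter": {"kind": "continuous", "sets": ["C1", "C2", "C3"]},
    "smoker": {"kind": "binary", "sets": ["C1", "C2", "C3"]},
    "n_stents": {"kind": "continuous", "sets": ["C1", "C2"]},
    "nyha_class": {"kind": "continuous", "sets": ["C1", "C2", "C3"]},
    "height": {"kind": "continuous", "sets": ["C1", "C2", "C3"]},
    "weight": {"kind": "continuous", "sets": ["C1", "C2", "C3"]},
    "plaques": {"kind": "binary", "sets": ["C1", "C2"]},
    "reference_diameter": {"kind": "continuous", "sets": ["C1", "C2", "C3"]},
    "st_elevation": {"kind": "binary", "sets": ["C2"]},
    "stenosis_type": {"kind": "categorical", "levels": ["de_novo", "restenotic", "in_stent"], "sets": ["C1", "C2"]},
    "thrombus": {"kind": "binary", "sets": ["C1"]},
    "timi_rating": {"kind": "continuous", "sets": ["C1", "C2", "C3"]},
    "tortuosity": {"kind": "binary", "sets": ["C1"]},
    "vessels_affected": {"kind": "continuous", "sets": ["C1", "C2", "C3"]}
  },
  "biomarkers": {
    "cholesterol": {"kind": "continuous", "sets": ["B1"]},
    "creatine_kinase": {"kind": "continuous", "sets": ["B1", "B2"]},
    "ck_mb": {"kind": "continuous", "sets": ["B1", "B2"]},
    "creatinine": {"kind": "continuous", "sets": ["B2", "B3"]},
    "crp": {"kind": "continuous", "sets": ["B1", "B2", "B3"]},
    "hdl": {"kind": "continuous", "sets": ["B1"]},
    "ldl": {"kind": "continuous", "sets": ["B1"]},
    "nt_probnp": {"kind": "continuous", "sets": ["B3"]},
    "triglycerides": {"kind": "continuous", "sets": ["B1"]},
    "troponin_t": {"kind": "continuous", "sets": ["B1", "B2", "B3"]},
    "hs_troponin_t": {"kind": "continuous", "sets": ["B3"]}
  }
}
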