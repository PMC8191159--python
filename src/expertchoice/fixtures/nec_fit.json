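{
  "schema_version": 1,
  "spec": {
    "schema_version": 1,
    "decision_label": "NEC surgery recommendation for a critically ill preterm neonate: operate yes/no",
    "response_type": "binary",
    "factors": [
      {"name": "sex", "levels": ["Boy", "Girl"], "coding": "dummy"},
      {"name": "gestational_age", "levels": ["24 wk", "26 wk", "28 wk", "30 wk"], "coding": "dummy"},
      {"name": "birth_weight", "levels": ["500 g", "650 g", "800 g", "1500 g"], "coding": "dummy"},
      {"name": "perinatal_asphyxia", "levels": ["Yes", "Dubious", "No"], "coding": "linear"},
      {"name": "congenital_comorbidity", "levels": ["Present with high impact", "Present with minor impact", "Absent"], "coding": "dummy"},
      {"name": "progress_before_nec", "levels": ["Serious complications", "Minor complications", "No complications"], "coding": "linear"},
      {"name": "postnatal_age", "levels": ["0-7 d", "7-14 d", "14-21 d"], "coding": "linear"},
      {"name": "weight_increase", "levels": ["Weak", "Intermediate", "Good"], "coding": "linear"},
      {"name": "cerebral_ultrasound", "levels": ["Bad prognosis", "Intermediate prognosis", "Good prognosis"], "coding": "dummy"},
      {"name": "lung_function", "levels": ["Weak", "Intermediate", "Good"], "coding": "linear"},
      {"name": "hemodynamic_status", "levels": ["Unstable despite maximal support", "Stable with support", "Stable without support"], "coding": "linear"},
      {"name": "cerebral_oxygen_nirs", "levels": ["40", "60", "80"], "coding": "linear"},
      {"name": "parental_preferences", "levels": ["In favor of comfort care", "Doubtful about surgery", "In favor of surgery"], "coding": "dummy"},
      {"name": "parental_capacities", "levels": ["Weak", "Intermediate", "Good"], "coding": "linear"}
    ]
  },
  "model_kind": "binary logit",
  "weights": {
    "const": -8.830,
    "sex[Girl]": 0.020,
    "gestational_age[26 wk]": 1.656,
    "gestational_age[28 wk]": 1.851,
    "gestational_age[30 wk]": 2.859,
    "birth_weight[650 g]": 1.238,
    "birth_weight[800 g]": 1.835,
    "birth_weight[1500 g]": 2.507,
    "perinatal_asphyxia": 0.452,
    "congenital_comorbidity[Present with minor impact]": 0.944,
    "congenital_comorbidity[Absent]": 1.752,
    "progress_before_nec": 0.230,
    "postnatal_age": 0.250,
    "weight_increase": 0.183,
    "cerebral_ultrasound[Intermediate prognosis]": 1.798,
    "cerebral_ultrasound[Good prognosis]": 2.782,
    "lung_function": 0.204,
    "hemodynamic_status": 0.279,
    "cerebral_oxygen_nirs": 0.430,
    "parental_preferences[Doubtful about surgery]": 1.729,
    "parental_preferences[In favor of surgery]": 2.154,
    "parental_capacities": 0.216
  },
  "p_values": {
    "const": 0.0005,
    "sex[Girl]": 0.96,
    "gestational_age[26 wk]": 0.0005,
    "gestational_age[28 wk]": 0.0005,
    "gestational_age[30 wk]": 0.0005,
    "birth_weight[650 g]": 0.003,
    "birth_weight[800 g]": 0.0005,
    "birth_weight[1500 g]": 0.0005,
    "perinatal_asphyxia": 0.053,
    "congenital_comorbidity[Present with minor impact]": 0.002,
    "congenital_comorbidity[Absent]": 0.0005,
    "progress_before_nec": 0.25,
    "postnatal_age": 0.28,
    "weight_increase": 0.36,
    "cerebral_ultrasound[Intermediate prognosis]": 0.0005,
    "cerebral_ultrasound[Good prognosis]": 0.0005,
    "lung_function": 0.29,
    "hemodynamic_status": 0.144,
    "cerebral_oxygen_nirs": 0.046,
    "parental_preferences[Doubtful about surgery]": 0.0005,
    "parental_preferences[In favor of surgery]": 0.0005,
    "parental_capacities": 0.28
  },
  "log_likelihood": -245.0,
  "null_log_likelihood": -364.0,
  "mcfadden_rho2": 0.326923076923077,
  "n_observations": 525
}
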