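schema_version: 1
decision_label: 'NEC surgery recommendation for a critically ill preterm neonate: operate yes/no'
response_type: binary
factors:
- name: sex
  levels: [Boy, Girl]
  coding: dummy
- name: gestational_age
  levels: [24 wk, 26 wk, 28 wk, 30 wk]
  coding: dummy
- name: birth_weight
  levels: [500 g, 650 g, 800 g, 1500 g]
  coding: dummy
- name: perinatal_asphyxia
  levels: ['Yes', Dubious, 'No']
  coding: linear
- name: congenital_comorbidity
  levels: [Present with high impact, Present with minor impact, Absent]
  coding: dummy
- name: progress_before_nec
  levels: [Serious complications, Minor complications, No complications]
  coding: linear
- name: postnatal_age
  levels: [0-7 d, 7-14 d, 14-21 d]
  coding: linear
- name: weight_increase
  levels: [Weak, Intermediate, Good]
  coding: linear
- name: cerebral_ultrasound
  levels: [Bad prognosis, Intermediate prognosis, Good prognosis]
  coding: dummy
- name: lung_function
  levels: [Weak, Intermediate, Good]
  coding: linear
- name: hemodynamic_status
  levels: [Unstable despite maximal support, Stable with support, Stable without support]
  coding: linear
- name: cerebral_oxygen_nirs
  levels: ['40', '60', '80']
  coding: linear
- name: parental_preferences
  levels: [In favor of comfort care, Doubtful about surgery, In favor of surgery]
  coding: dummy
- name: parental_capacities
  levels: [Weak, Intermediate, Good]
  coding: linear
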