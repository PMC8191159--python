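profile_id,sex,gestational_age,birth_weight,perinatal_asphyxia,congenital_comorbidity,progress_before_nec,postnatal_age,weight_increase,cerebral_ultrasound,lung_function,hemodynamic_status,cerebral_oxygen_nirs,parental_preferences,parental_capacities
worst,Boy,24 wk,500 g,Yes,Present with high impact,Serious complications,0-7 d,Weak,Bad prognosis,Weak,Unstable despite maximal support,40,In favor of comfort care,Weak
intermediate,Boy,26 wk,800 g,Dubious,Present with minor impact,Minor complications,7-14 d,Intermediate,Intermediate prognosis,Intermediate,Stable with support,60,Doubtful about surgery,Intermediate
best,Girl,30 wk,1500 g,No,Absent,No complications,14-21 d,Good,Good prognosis,Good,Stable without support,80,In favor of surgery,Good
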