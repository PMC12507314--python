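# Coded vocabulary of "other complications" recorded during the QCI period, v1.
# One code per line; lines starting with '#' are ignored.
# Codes marked [tbsa20-exempt] are not counted as complications in patients
# with TBSA >= 20%, where they occur frequently as part of the expected course.
pressure_ulcer_staging
ards  # [tbsa20-exempt] acute respiratory distress syndrome
vanishing_graft
wound_enlargement
psychotic_behavior_delirium
polyneuropathy  # [tbsa20-exempt]
other_neurological_injury
bleeding_ulcer
paralytic_ileus
pressure_ulcer
urinary_tract_infection
other_tract
other_urogenital
partial_graft_take
diabetes_after_trauma
other_endocrine
pneumothorax
pulmonary_embolism
other_pulmonary
thrombosis
embolism
acute_renal_failure
ischemia
arrhythmia
other_circulatory
bronchopneumonia
aspiration_pneumonia
other_complication
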