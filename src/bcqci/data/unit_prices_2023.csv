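item_code,label,category,price_eur,price_year,unit
icu_day,ICU burn center day,burn_center_stay,3894.00,2023,day
non_icu_day,Non-ICU burn center day,burn_center_stay,1245.00,2023,day
readmission_day,Readmission hospital day,burn_center_stay,1245.00,2023,day
day_care,Day care contact,burn_center_stay,280.00,2023,session
diagnostics,Diagnostic procedure,treatment,120.00,2023,procedure
wound_care_session,Inpatient wound dressing session,treatment,95.00,2023,session
surgical_procedure,Surgical treatment (escharotomy/excision/grafting),treatment,2890.00,2023,procedure
blood_product,Blood product unit,treatment,230.00,2023,item
pressure_garment,Pressure garment set,treatment,430.00,2023,item
silicone_therapy,Silicone therapy item,treatment,45.00,2023,item
splint,Splint,treatment,150.00,2023,item
clinical_consultation,Clinical burn consultation,clinical_consultation,97.00,2023,consultation
outpatient_wound_care,Outpatient wound care visit,outpatient_burn_care,80.00,2023,consultation
outpatient_scar_care,Outpatient scar care visit,outpatient_burn_care,60.00,2023,consultation
aftercare_nurse,Aftercare nurse contact,outpatient_burn_care,42.00,2023,consultation
plastic_surgeon,Outpatient plastic surgeon visit,outpatient_burn_care,80.00,2023,consultation
outpatient_other,Other outpatient burn care contact,outpatient_burn_care,65.00,2023,consultation
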