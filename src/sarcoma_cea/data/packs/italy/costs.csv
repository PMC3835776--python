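resource,unit,cost_eur,vial_strength_mg
biopsy,per procedure,129.1,
chest_xray,per scan,16.2,
ct_scan,per scan,86.3,
echocardiography,per assessment,51.7,
haematology_tests,per panel,3.7,
hospitalisation_day,per day,238.3,
liver_function_test,per test,9.2,
manage_anaemia,per episode,1354.8,
manage_febrile_neutropenia,per episode,3305.0,
manage_neutropenia,per episode,523.3,
manage_thrombocytopenia,per episode,1354.8,
mdt_assessment,per assessment,48.7,
mri_scan,per scan,285.8,
oncologist_visit,per visit,21.6,
outpatient_attendance,per attendance,122.8,
palliative_care,per patient,3265.0,
pet_scan,per scan,1071.7,
radiotherapist_visit,per visit,21.6,
renal_function_test,per test,5.0,
ultrasound,per scan,17.6,
urinalysis,per test,6.1,
granisetron_pack,per pack (1 mg x 10),133.9,
ondansetron_pack,per pack (4 mg x 6),57.8,
dexamethasone_pack,per pack (0.75 mg x 10),1.1,
filgrastim_6mg,per dose,149.8,
docetaxel,per vial,84.4,10
doxorubicin,per vial,119.5,50
epirubicin,per vial,81.2,50
gemcitabine,per vial,113.2,1000
ifosfamide,per vial,30.7,1000
liposomal_doxorubicin,per vial,548.2,2
mesna,per vial,25.7,6000
trabectedin,per vial,2970.1,1
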