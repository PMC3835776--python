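resource,unit,cost_eur,vial_strength_mg
biopsy,per procedure,314.1,
chest_xray,per scan,48.7,
ct_scan,per scan,313.6,
echocardiography,per assessment,214.9,
electrocardiogram,per test,334.2,
haematology_tests,per panel,5.2,
hospitalisation_day,per day,288.6,
manage_anaemia,per episode,548.6,
manage_febrile_neutropenia,per episode,2892.0,
manage_thrombocytopenia,per episode,548.6,
mdt_assessment,per assessment,1816.5,
mri_scan,per scan,386.4,
oncologist_visit,per visit,283.7,
outpatient_attendance,per attendance,288.6,
palliative_care,per patient,1343.9,
pet_scan,per scan,314.1,
urinalysis,per test,20.9,
betamethasone_8mg,per dose,3.2,
tropisetron_5mg,per dose,20.5,
betapred_4mg,per dose,6.4,
aprepitant_125mg,per dose,63.8,
pegfilgrastim_syringe,per syringe,1322.5,
cyclophosphamide,per vial,4.1,200
dacarbazine,per vial,8.9,200
docetaxel,per vial,403.1,80
doxorubicin,per vial,59.8,50
etoposide,per vial,20.8,100
gemcitabine,per vial,104.6,1000
ifosfamide,per vial,65.7,2000
mesna,per vial,192.2,5000
trabectedin,per vial,1913.3,1
trofosfamide,per unit (50 mg/m2),1.4,90
vincristine,per vial,16.2,1
vinorelbine,per vial (1 mL),24.1,10
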