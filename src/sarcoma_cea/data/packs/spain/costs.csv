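resource,unit,cost_eur,vial_strength_mg
biopsy,per procedure,603.7,
bone_scintigraphy,per scan,296.8,
chest_xray,per scan,6.5,
ct_scan,per scan,87.5,
echocardiography,per assessment,18.2,
haematology_tests,per panel,20.5,
hospitalisation_day,per day,212.9,
liver_function_test,per test,11.7,
manage_anaemia,per episode,900.0,
manage_febrile_neutropenia,per episode,3829.5,
manage_neutropenia,per episode,2086.1,
manage_thrombocytopenia,per episode,900.0,
mdt_assessment,per assessment,61.3,
mri_scan,per scan,168.0,
oncologist_visit,per visit,61.5,
outpatient_attendance,per attendance,98.9,
palliative_care,per patient,2167.7,
pet_scan,per scan,500.0,
radiotherapist_visit,per visit,61.5,
renal_function_test,per test,8.9,
ultrasound,per scan,18.2,
urinalysis,per test,1.8,
palonosetron_250mcg,per vial,104.6,
aprepitant_125mg,per dose,90.9,
granisetron_pack,per pack (1 mg x 10),48.1,
metoclopramide_250ml,per bottle,2.7,
ondansetron_pack,per pack (4 mg x 15),36.3,
dexamethasone_pack,per pack (1 mg x 30),3.0,
diphenhydramine_pack,per pack (25 mg x 25),1.4,
pegfilgrastim_syringe,per syringe,1062.6,
dacarbazine,per vial,21.7,1000
docetaxel,per vial,182.8,100
doxorubicin,per vial,4.1,50
gemcitabine,per vial,75.7,1000
ifosfamide,per vial,19.7,1000
mesna,per vial,13.2,3000
paclitaxel,per vial,83.8,30
trabectedin,per vial,2049.9,1
vinorelbine,per vial (1 mL),24.1,10
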