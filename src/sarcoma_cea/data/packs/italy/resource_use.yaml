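bsa_m2: 1.8
diagnosis:
  visits:
    oncologist_visit: 3
    mdt_assessment: 1
  tests:
    haematology_tests: 1.0
    urinalysis: 1.0
    biopsy: 0.75
    ct_scan: 0.875
    mri_scan: 0.6
    pet_scan: 0.2
    chest_xray: 0.15
    ultrasound: 0.275
evaluation_tests:
  haematology_tests: 1.0
  ct_scan: 0.8
  mri_scan: 0.3
  pet_scan: 0.1
  ultrasound: 0.1
  chest_xray: 0.08
per_cycle_tests:
  all:
    haematology_tests: 1.0
    renal_function_test: 1.0
  conditional:
  - condition: contains:trabectedin
    tests:
      liver_function_test: 1.0
per_course_tests:
- condition: contains_any:doxorubicin,epirubicin,liposomal_doxorubicin
  tests:
    echocardiography: 1.0
followup:
  interval_months: 4.5
  tests:
    haematology_tests: 1.0
    ct_scan: 0.75
    mri_scan: 0.375
    pet_scan: 0.125
    chest_xray: 0.08
    ultrasound: 0.005
  visits:
    oncologist_visit: 1
    radiotherapist_visit: 1
dose_reduction:
  uptake: 0.18
  magnitude: 0.23
  from_course_cycle: 4
palliative:
  one_off: true
premedication:
- cost_key: granisetron_pack
  quantity: 0.3
  proportion: 0.5
  condition: all
- cost_key: ondansetron_pack
  quantity: 0.3333
  proportion: 0.5
  condition: all
- cost_key: dexamethasone_pack
  quantity: 1.3333
  proportion: 1.0
  condition: all
gcsf:
  cost_key: filgrastim_6mg
  quantity: 1.0
  uptake:
  - condition: regimen:doxorubicin_ifosfamide
    proportion: 0.65
  - condition: contains:gemcitabine
    proportion: 0.15
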