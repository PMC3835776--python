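regimen,drug,dose_per_m2_mg,admission_days,outpatient_attendances,oral,line
cyvadic,cyclophosphamide,600,0,4,0,second
cyvadic,vincristine,1,0,4,0,second
cyvadic,doxorubicin,30,0,4,0,second
cyvadic,dacarbazine,250,0,4,0,second
docetaxel,docetaxel,100,0,1,0,second
doxorubicin,doxorubicin,75,0,1,0,second
doxorubicin_ifosfamide,doxorubicin,66,4.0,0,0,both
doxorubicin_ifosfamide,ifosfamide,8500,4.0,0,0,both
ifosfamide,ifosfamide,12500,2.0,1.0,0,second
ifosfamide_epirubicin,epirubicin,100,3,0,0,second
ifosfamide_epirubicin,ifosfamide,5000,3,0,0,second
gemcitabine,gemcitabine,1000,0,2,0,second
gemcitabine_dacarbazine,gemcitabine,1766,0,2,0,second
gemcitabine_dacarbazine,dacarbazine,700,0,2,0,second
gemcitabine_docetaxel,gemcitabine,1000,0,2,0,second
gemcitabine_docetaxel,docetaxel,75,0,2,0,second
gemcitabine_paclitaxel,gemcitabine,1000,0,2,0,second
gemcitabine_paclitaxel,paclitaxel,125,0,2,0,second
gemcitabine_vinorelbine,gemcitabine,1250,0,2,0,second
gemcitabine_vinorelbine,vinorelbine,25,0,2,0,second
liposomal_doxorubicin,liposomal_doxorubicin,50,0,1,0,second
trabectedin,trabectedin,1.3,2,0,0,both
trofosfamide,trofosfamide,200,0,0,1,second
trofosfamide_etoposide,trofosfamide,150,0,0,1,second
trofosfamide_etoposide,etoposide,25,0,0,1,second
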