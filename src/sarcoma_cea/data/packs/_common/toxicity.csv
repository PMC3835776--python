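regimen,line,p_neutropenia,p_febrile_neutropenia,p_thrombocytopenia,p_anaemia,imputed
doxorubicin_ifosfamide,first,0.82,0.12,0.23,0.35,0
trabectedin,first,0.33,0.0,0.0,0.03,0
cyvadic,second,0.52,0.19,0.17,0.16,1
docetaxel,second,0.9,0.12,0.03,0.08,0
doxorubicin,second,0.84,0.19,0.09,0.18,0
doxorubicin_ifosfamide,second,0.52,0.19,0.17,0.18,1
gemcitabine,second,0.18,0.07,0.18,0.11,0
gemcitabine_dacarbazine,second,0.46,0.19,0.12,0.23,0
gemcitabine_docetaxel,second,0.31,0.09,0.33,0.18,0
gemcitabine_paclitaxel,second,0.52,0.19,0.17,0.16,1
gemcitabine_vinorelbine,second,0.38,0.08,0.1,0.05,0
ifosfamide,second,0.82,0.39,0.13,0.12,0
ifosfamide_epirubicin,second,0.52,0.19,0.17,0.18,1
liposomal_doxorubicin,second,0.07,0.02,0.0,0.35,1
trabectedin,second,0.5,0.06,0.16,0.18,0
trofosfamide,second,0.52,0.19,0.17,0.25,1
trofosfamide_etoposide,second,0.52,0.19,0.17,0.16,1
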