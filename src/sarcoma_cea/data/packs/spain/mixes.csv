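first_line,second_line,probability
doxorubicin_ifosfamide,cyvadic,<0.01
doxorubicin_ifosfamide,gemcitabine_dacarbazine,0.12
doxorubicin_ifosfamide,gemcitabine_docetaxel,0.2
doxorubicin_ifosfamide,gemcitabine_paclitaxel,0.1
doxorubicin_ifosfamide,gemcitabine_vinorelbine,0.08
doxorubicin_ifosfamide,gemcitabine,0.12
doxorubicin_ifosfamide,ifosfamide,0.12
doxorubicin_ifosfamide,liposomal_doxorubicin,<0.01
doxorubicin_ifosfamide,trofosfamide,<0.01
doxorubicin_ifosfamide,trabectedin,0.26
trabectedin,docetaxel,<0.01
trabectedin,doxorubicin_ifosfamide,<0.01
trabectedin,doxorubicin,<0.01
trabectedin,gemcitabine_docetaxel,0.44
trabectedin,ifosfamide_epirubicin,<0.01
trabectedin,ifosfamide,0.56
trabectedin,trofosfamide_etoposide,<0.01
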