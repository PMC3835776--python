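regimen,line,p_cr,p_pr,p_sd,p_pd,dur_cr,dur_pr,dur_sd,imputed_probs,imputed_durs
doxorubicin_ifosfamide,first,0.06,0.21,0.38,0.35,15.44,7.69,6.41,0,0
trabectedin,first,0.03,0.11,0.14,0.72,17.74,8.75,7.48,0,0
cyvadic,second,0.03,0.19,0.39,0.39,12.13,6.57,5.75,1,1
docetaxel,second,0.0,0.11,0.25,0.64,0.0,6.6,7.17,0,0
doxorubicin,second,0.02,0.07,0.31,0.61,12.13,6.57,5.75,0,1
doxorubicin_ifosfamide,second,0.05,0.27,0.37,0.31,12.13,6.57,5.75,0,1
gemcitabine,second,0.0,0.08,0.33,0.59,0.0,4.46,3.86,0,0
gemcitabine_dacarbazine,second,0.01,0.1,0.39,0.51,10.48,6.5,5.79,0,0
gemcitabine_docetaxel,second,0.05,0.19,0.41,0.35,12.13,6.57,5.75,0,1
gemcitabine_paclitaxel,second,0.03,0.19,0.39,0.39,12.13,6.57,5.75,1,1
gemcitabine_vinorelbine,second,0.02,0.1,0.1,0.78,16.1,16.1,9.6,0,0
ifosfamide,second,0.02,0.13,0.24,0.61,13.77,8.75,7.61,0,0
ifosfamide_epirubicin,second,0.05,0.27,0.37,0.31,12.13,6.57,5.75,1,1
liposomal_doxorubicin,second,0.02,0.07,0.31,0.61,12.13,6.57,5.75,1,1
trabectedin,second,0.005,0.07,0.44,0.49,16.14,10.25,8.91,0,0
trofosfamide,second,0.0,0.03,0.19,0.79,12.13,6.57,5.75,0,1
trofosfamide_etoposide,second,0.03,0.19,0.39,0.39,12.13,6.57,5.75,1,1
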