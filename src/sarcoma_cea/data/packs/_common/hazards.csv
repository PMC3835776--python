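regimen,line,rate_per_month
doxorubicin_ifosfamide,first,0.042
trabectedin,first,0.032
docetaxel,second,0.036
gemcitabine,second,0.046
gemcitabine_vinorelbine,second,0.042
ifosfamide,second,0.032
trabectedin,second,0.031
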