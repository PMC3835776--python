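country,strategy,qalys
italy,doxorubicin_ifosfamide,0.595
italy,trabectedin,0.530
spain,doxorubicin_ifosfamide,0.590
spain,trabectedin,0.550
sweden,doxorubicin_ifosfamide,0.608
sweden,trabectedin,0.584
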