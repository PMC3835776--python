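country,strategy,category,amount_eur
italy,doxorubicin_ifosfamide,diagnosis,634.4
italy,doxorubicin_ifosfamide,first_line_cytotoxics,2302.9
italy,doxorubicin_ifosfamide,second_line_cytotoxics,17007.3
italy,doxorubicin_ifosfamide,evaluations,2025.7
italy,doxorubicin_ifosfamide,hospitalisation,5093.0
italy,doxorubicin_ifosfamide,outpatient,291.3
italy,doxorubicin_ifosfamide,cycle_tests,212.5
italy,doxorubicin_ifosfamide,premedication,5706.9
italy,doxorubicin_ifosfamide,palliative_care,2918.9
italy,doxorubicin_ifosfamide,toxicity_management,2728.6
italy,doxorubicin_ifosfamide,total,38921.7
italy,trabectedin,diagnosis,634.4
italy,trabectedin,first_line_cytotoxics,26885.4
italy,trabectedin,second_line_cytotoxics,2556.9
italy,trabectedin,evaluations,1641.7
italy,trabectedin,hospitalisation,3765.6
italy,trabectedin,outpatient,338.0
italy,trabectedin,cycle_tests,118.0
italy,trabectedin,premedication,1107.3
italy,trabectedin,palliative_care,1773.3
italy,trabectedin,toxicity_management,1811.1
italy,trabectedin,total,40631.7
spain,doxorubicin_ifosfamide,diagnosis,1886.5
spain,doxorubicin_ifosfamide,first_line_cytotoxics,1491.8
spain,doxorubicin_ifosfamide,second_line_cytotoxics,6524.1
spain,doxorubicin_ifosfamide,evaluations,1280.4
spain,doxorubicin_ifosfamide,hospitalisation,4704.7
spain,doxorubicin_ifosfamide,outpatient,560.9
spain,doxorubicin_ifosfamide,cycle_tests,266.2
spain,doxorubicin_ifosfamide,premedication,7621.1
spain,doxorubicin_ifosfamide,palliative_care,1942.7
spain,doxorubicin_ifosfamide,toxicity_management,4421.0
spain,doxorubicin_ifosfamide,total,30699.4
spain,trabectedin,diagnosis,1886.5
spain,trabectedin,first_line_cytotoxics,18432.1
spain,trabectedin,second_line_cytotoxics,1761.6
spain,trabectedin,evaluations,1098.7
spain,trabectedin,hospitalisation,3564.3
spain,trabectedin,outpatient,423.4
spain,trabectedin,cycle_tests,197.9
spain,trabectedin,premedication,1665.8
spain,trabectedin,palliative_care,1932.3
spain,trabectedin,toxicity_management,3233.7
spain,trabectedin,total,34196.3
sweden,doxorubicin_ifosfamide,diagnosis,2416.8
sweden,doxorubicin_ifosfamide,first_line_cytotoxics,3172.2
sweden,doxorubicin_ifosfamide,second_line_cytotoxics,8469.5
sweden,doxorubicin_ifosfamide,evaluations,2758.0
sweden,doxorubicin_ifosfamide,hospitalisation,4326.8
sweden,doxorubicin_ifosfamide,outpatient,998.6
sweden,doxorubicin_ifosfamide,cycle_tests,244.3
sweden,doxorubicin_ifosfamide,premedication,11732.4
sweden,doxorubicin_ifosfamide,palliative_care,1200.9
sweden,doxorubicin_ifosfamide,toxicity_management,1187.2
sweden,doxorubicin_ifosfamide,total,36506.7
sweden,trabectedin,diagnosis,2416.8
sweden,trabectedin,first_line_cytotoxics,17934.5
sweden,trabectedin,second_line_cytotoxics,3224.8
sweden,trabectedin,evaluations,2453.2
sweden,trabectedin,hospitalisation,3685.2
sweden,trabectedin,outpatient,439.0
sweden,trabectedin,cycle_tests,217.0
sweden,trabectedin,premedication,7458.6
sweden,trabectedin,palliative_care,1265.9
sweden,trabectedin,toxicity_management,685.2
sweden,trabectedin,total,39780.2
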