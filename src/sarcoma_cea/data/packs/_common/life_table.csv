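age,annual_mortality
65,0.02
66,0.022
67,0.0242
68,0.02662
69,0.029282
70,0.03221
71,0.035431
72,0.038974
73,0.042872
74,0.047159
75,0.051875
76,0.057062
77,0.062769
78,0.069045
79,0.07595
80,0.083545
81,0.091899
82,0.101089
83,0.111198
84,0.122318
85,0.13455
86,0.148005
87,0.162805
88,0.179086
89,0.196995
90,0.216694
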