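# label: multi_lsa
# syringe_capacity_uL: 40
time_s,volume_uL,syringe_conc_uM
250,1,1000
310,1,1000
370,1,1000
430,1,1000
490,1,1000
550,1,1000
610,1,1000
670,1,1000
730,1,1000
790,1,1000
850,1,1000
910,1,1000
970,1,1000
1030,1,1000
1090,1,1000
1150,1,1000
1210,1,1000
1270,1,1000
1330,1,1000
1390,1,1000
1450,1,1000
1510,1,1000
1570,1,1000
1630,1,1000
1690,1,1000
1750,1,1000
1810,1,1000
1870,1,1000
1930,1,1000
1990,1,1000
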