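# label: single_lsa
# syringe_capacity_uL: 40
time_s,volume_uL,syringe_conc_uM
250,5,100
1250,5,100
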