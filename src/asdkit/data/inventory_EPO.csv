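group,count
C_CH3,1
CH2,2.5
COO,1
CH3,1.25
N_CH2,0.5
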