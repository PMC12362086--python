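group,count
CH2,3.8
N_CH2,0.6
CO,0.6
ring,0.6
CH3,0.4
COO,0.4
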