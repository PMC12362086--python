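group,count
CH2,5
N_CH2,1
CO,1
ring,1
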