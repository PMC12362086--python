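group,count
ring,1
O,2
OH,1
CH2,3
CH3,0.5
COO,0.5
COOH,0.3
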