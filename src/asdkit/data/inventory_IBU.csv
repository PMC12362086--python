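group,count
CH3,1
CH2,1
CH_CH3,2
phenylene_p,1
COOH,1
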