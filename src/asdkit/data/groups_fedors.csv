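group,E,Fd,Fp,Eh,V
CH3,4710,,,,33.5
CH2,4940,,,,16.1
CH_CH3,8140,,,,32.5
C_CH3,6180,,,,14.3
phenyl,31940,,,,71.4
phenylene_p,31940,,,,52.4
COOH,27630,,,,28.5
COO,18000,,,,18.0
CO,17370,,,,10.8
OH,29800,,,,10.0
O,3350,,,,3.8
N_CH2,9130,,,,7.1
ring,1050,,,,16.0
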